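"""Synthetic two-subsystem panel generator with a known latent VAR.

The generator produces balanced province-by-year indicator panels whose
*latent* subsystem levels follow a bivariate fixed-effects VAR(2)

    Y[i,t] = A1 Y[i,t-1] + A2 Y[i,t-2] + c + mu[i] + lam[t] + eps[i,t]

with Gaussian unit effects mu[i], time effects lam[t] and innovations
eps[i,t].  The intercept c = (I - A1 - A2) @ level_offsets pins the
stationary mean of each channel at its level offset, which keeps the
latent levels (and hence the derived indicators) positive.  Observable
indicators are noisy linear readouts of the latent levels, mimicking the
structure of the yearbook workforce table (4 indicators) and the
search-interest table (8 indicators).

Because the data-generating process is fully known, every downstream
stage — entropy scoring, panel-VAR estimation, Granger tests, coupling
classification — can be validated for recovery, size and power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .indexspec import IndexSpec

SUBSYSTEMS = ("VHR", "PAAW")  # row order of all 2x2 lag matrices
POSITIVITY_EPS = 1e-6

__all__ = [
    "DGPSpec",
    "DGPTruth",
    "simulate_latent",
    "latent_to_indicators",
    "simulate_panel",
    "preset_regimes",
    "companion_matrix",
    "spectral_radius",
    "write_truth",
]


@dataclass(frozen=True)
class IndicatorLoading:
    """Linear readout of one indicator from its subsystem's latent level."""

    loading: float
    noise_sd: float
    attribute: str = "+"

    def __post_init__(self) -> None:
        if self.loading <= 0:
            raise ValueError("indicator loading must be > 0")
        if self.noise_sd < 0:
            raise ValueError("indicator noise_sd must be >= 0")
        if self.attribute not in ("+", "-"):
            raise ValueError("attribute must be '+' or '-'")


def _default_loadings() -> dict[str, tuple[IndicatorLoading, ...]]:
    # 4 workforce-like and 8 search-index-like indicators, loadings spread
    # around 1 so no single indicator dominates, modest measurement noise.
    rng = [0.8, 1.0, 1.2, 1.5, 0.7, 0.9, 1.1, 1.3]
    return {
        "VHR": tuple(IndicatorLoading(l, 0.15) for l in rng[:4]),
        "PAAW": tuple(IndicatorLoading(l, 0.15) for l in rng),
    }


@dataclass(frozen=True)
class DGPSpec:
    """Complete description of the synthetic data-generating process."""

    n_units: int = 31
    n_periods: int = 10
    A1: np.ndarray = field(
        default_factory=lambda: np.diag([0.4, 0.4]).astype(float))
    A2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    unit_effect_sd: float = 0.5
    time_effect_sd: float = 0.3
    innovation_cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    indicator_loadings: dict[str, tuple[IndicatorLoading, ...]] = field(
        default_factory=_default_loadings)
    level_offsets: tuple[float, float] = (10.0, 10.0)
    seed: int = 0
    burn_in: int = 50
    stationary: bool = True
    start_year: int = 2014

    def __post_init__(self) -> None:
        object.__setattr__(self, "A1", np.asarray(self.A1, dtype=float))
        object.__setattr__(self, "A2", np.asarray(self.A2, dtype=float))
        object.__setattr__(
            self, "innovation_cov", np.asarray(self.innovation_cov, dtype=float))
        if self.A1.shape != (2, 2) or self.A2.shape != (2, 2):
            raise ValueError("A1 and A2 must be 2x2 matrices")
        if self.innovation_cov.shape != (2, 2):
            raise ValueError("innovation_cov must be 2x2")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ValueError("innovation_cov must be symmetric")
        if np.linalg.eigvalsh(self.innovation_cov).min() < -1e-12:
            raise ValueError("innovation_cov must be positive semidefinite")
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        if self.n_periods < 4:  # p + 2 for the targeted lag order p = 2
            raise ValueError("n_periods must be >= 4 (lag order + 2)")
        if min(self.unit_effect_sd, self.time_effect_sd) < 0:
            raise ValueError("effect standard deviations must be >= 0")
        if set(self.indicator_loadings) != set(SUBSYSTEMS):
            raise ValueError(
                f"indicator_loadings must cover exactly {SUBSYSTEMS}")
        if self.stationary:
            rho = spectral_radius(self.A1, self.A2)
            if rho >= 1.0:
                raise ValueError(
                    "spec is flagged stationary but the companion matrix has "
                    f"spectral radius {rho:.4f} >= 1"
                )

    def index_spec(self) -> IndexSpec:
        """Anonymous IndexSpec matching this DGP's indicator layout."""
        from .indexspec import Indicator

        subs = {
            name: tuple(
                Indicator(
                    id=f"{name}_{k + 1}",
                    label=f"synthetic {name} indicator {k + 1}",
                    attribute=ld.attribute,
                )
                for k, ld in enumerate(loadings)
            )
            for name, loadings in self.indicator_loadings.items()
        }
        return IndexSpec(subsystems=subs)


@dataclass(frozen=True)
class DGPTruth:
    """Ground truth realised by one simulation run."""

    latent_scores: pd.DataFrame  # long: unit, year, subsystem, score
    spec: DGPSpec
    unit_effects: np.ndarray     # (n_units, 2)
    time_effects: np.ndarray     # (n_periods, 2), post burn-in
    latent: np.ndarray           # (n_units, n_periods, 2) convenience array


def companion_matrix(A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    """Stack (A1, A2) into the 4x4 VAR(2) companion form."""
    A1 = np.asarray(A1, float)
    A2 = np.asarray(A2, float)
    top = np.hstack([A1, A2])
    bottom = np.hstack([np.eye(2), np.zeros((2, 2))])
    return np.vstack([top, bottom])


def spectral_radius(A1: np.ndarray, A2: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(A1, A2))).max())


def simulate_latent(spec: DGPSpec) -> DGPTruth:
    """Run the latent VAR(2) recursion and discard the burn-in.

    Same spec (including seed) always returns identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, T, burn = spec.n_units, spec.n_periods, spec.burn_in
    total = T + burn
    offsets = np.asarray(spec.level_offsets, float)
    intercept = (np.eye(2) - spec.A1 - spec.A2) @ offsets

    mu = rng.normal(0.0, spec.unit_effect_sd, size=(n, 2)) \
        if spec.unit_effect_sd > 0 else np.zeros((n, 2))
    lam = rng.normal(0.0, spec.time_effect_sd, size=(total, 2)) \
        if spec.time_effect_sd > 0 else np.zeros((total, 2))

    if np.allclose(spec.innovation_cov, 0.0):
        eps = np.zeros((n, total, 2))
    else:
        chol = np.linalg.cholesky(
            spec.innovation_cov + 1e-15 * np.eye(2))
        eps = rng.standard_normal((n, total, 2)) @ chol.T

    Y = np.empty((n, total + 2, 2))
    Y[:, 0, :] = offsets  # start at the stationary mean
    Y[:, 1, :] = offsets
    for t in range(total):
        Y[:, t + 2, :] = (
            Y[:, t + 1, :] @ spec.A1.T
            + Y[:, t, :] @ spec.A2.T
            + intercept
            + mu
            + lam[t]
            + eps[:, t, :]
        )
    kept = Y[:, 2 + burn:, :]  # (n, T, 2)

    units = [f"P{k + 1:02d}" for k in range(n)]
    years = np.arange(spec.start_year, spec.start_year + T)
    long = pd.DataFrame(
        {
            "unit": np.repeat(units, T * 2),
            "year": np.tile(np.repeat(years, 2), n),
            "subsystem": np.tile(list(SUBSYSTEMS), n * T),
            "score": kept.reshape(-1),
        }
    )
    return DGPTruth(
        latent_scores=long,
        spec=spec,
        unit_effects=mu,
        time_effects=lam[burn:],
        latent=kept,
    )


def latent_to_indicators(truth: DGPTruth, spec: DGPSpec | None = None
                         ) -> pd.DataFrame:
    """Emit the observable long-format indicator panel.

    Benefit-type ("+") indicators are ``loading * latent + noise``;
    cost-type ("-") indicators are reflected about twice the subsystem's
    level offset (``loading * (2*offset - latent) + noise``) so they
    decrease in the latent level while staying on a positive scale.
    All values are clipped below at a small epsilon to guarantee strict
    positivity for the entropy normalisation.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n, T = spec.n_units, spec.n_periods
    units = [f"P{k + 1:02d}" for k in range(n)]
    years = np.arange(spec.start_year, spec.start_year + T)

    frames = []
    for s_idx, name in enumerate(SUBSYSTEMS):
        latent = truth.latent[:, :, s_idx]  # (n, T)
        offset = spec.level_offsets[s_idx]
        for k, ld in enumerate(spec.indicator_loadings[name]):
            base = latent if ld.attribute == "+" else (2.0 * offset - latent)
            vals = ld.loading * base
            if ld.noise_sd > 0:
                vals = vals + rng.normal(0.0, ld.noise_sd, size=vals.shape)
            vals = np.clip(vals, POSITIVITY_EPS, None)
            frames.append(pd.DataFrame(
                {
                    "unit": np.repeat(units, T),
                    "year": np.tile(years, n),
                    "subsystem": name,
                    "indicator": f"{name}_{k + 1}",
                    "value": vals.reshape(-1),
                }
            ))
    panel = pd.concat(frames, ignore_index=True)
    return panel.sort_values(
        ["subsystem", "indicator", "unit", "year"], ignore_index=True)


def simulate_panel(spec: DGPSpec) -> tuple[pd.DataFrame, DGPTruth]:
    """Convenience: latent simulation plus indicator readout in one call."""
    truth = simulate_latent(spec)
    return latent_to_indicators(truth), truth


PRESET_NAMES = ("null", "unidirectional_vhr_to_paaw", "bidirectional",
                "unit_root")


def preset_regimes(name: str, **overrides) -> DGPSpec:
    """Named data-generating regimes for the study's qualitative findings.

    - ``null``: no cross-lags; each subsystem an independent AR process
      (A1 = diag(0.4, 0.4), A2 = 0).  Used for test size.
    - ``unidirectional_vhr_to_paaw``: workforce capacity drives public
      attention (nonzero PAAW-equation coefficients on lagged VHR, zero
      reverse cross-lags), the pattern reported for the real panel.
    - ``bidirectional``: cross-lags in both directions.
    - ``unit_root``: random-walk channels (companion spectral radius 1),
      for stationarity-screening tests; carries ``stationary=False``.
    """
    if name == "null":
        spec = DGPSpec(A1=np.diag([0.4, 0.4]), A2=np.zeros((2, 2)))
    elif name == "unidirectional_vhr_to_paaw":
        spec = DGPSpec(
            A1=np.array([[0.45, 0.0], [0.40, 0.30]]),
            A2=np.array([[0.10, 0.0], [0.20, 0.05]]),
        )
    elif name == "bidirectional":
        spec = DGPSpec(
            A1=np.array([[0.40, 0.20], [0.25, 0.35]]),
            A2=np.array([[0.05, 0.10], [0.10, 0.05]]),
        )
    elif name == "unit_root":
        spec = DGPSpec(A1=np.eye(2), A2=np.zeros((2, 2)), stationary=False)
    else:
        raise ValueError(
            f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
    return replace(spec, **overrides) if overrides else spec


def write_truth(truth: DGPTruth, path: str | Path) -> None:
    """Write a JSON sidecar with the spec and realised effects."""
    spec = truth.spec
    payload = {
        "spec": {
            "n_units": spec.n_units,
            "n_periods": spec.n_periods,
            "A1": spec.A1.tolist(),
            "A2": spec.A2.tolist(),
            "unit_effect_sd": spec.unit_effect_sd,
            "time_effect_sd": spec.time_effect_sd,
            "innovation_cov": spec.innovation_cov.tolist(),
            "level_offsets": list(spec.level_offsets),
            "seed": spec.seed,
            "burn_in": spec.burn_in,
            "stationary": spec.stationary,
            "start_year": spec.start_year,
            "indicator_loadings": {
                name: [
                    {"loading": ld.loading, "noise_sd": ld.noise_sd,
                     "attribute": ld.attribute}
                    for ld in loadings
                ]
                for name, loadings in spec.indicator_loadings.items()
            },
        },
        "unit_effects": truth.unit_effects.tolist(),
        "time_effects": truth.time_effects.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
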