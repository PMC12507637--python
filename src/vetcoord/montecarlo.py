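"""Monte-Carlo studies over the synthetic data-generating regimes.

These loops run the *whole* analysis chain — latent VAR simulation,
indicator readout, per-year entropy scoring, fixed-effects panel-VAR
estimation, Granger tests — many times against a known regime, which is
how the package quantifies test size, power and estimator bias under the
study's panel dimensions (31 provinces, 10 years by default).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import pvar as pv
from . import simulate as sim
from .entropy import score_cross_section

__all__ = ["scored_array", "granger_rejection_rates", "coefficient_means"]


def scored_array(spec: sim.DGPSpec) -> np.ndarray:
    """Simulate one panel and entropy-score it, returning (units, T, 2).

    Equivalent to ``simulate_panel`` + ``score_panel`` but on arrays, so
    replicated studies stay cheap.  Subsystem order follows
    :data:`vetcoord.simulate.SUBSYSTEMS`.
    """
    truth = sim.simulate_latent(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n, T = spec.n_units, spec.n_periods
    Y = np.empty((n, T, 2))
    for s_idx, name in enumerate(sim.SUBSYSTEMS):
        latent = truth.latent[:, :, s_idx]
        offset = spec.level_offsets[s_idx]
        lds = spec.indicator_loadings[name]
        X = np.empty((n, T, len(lds)))
        attrs = []
        for k, ld in enumerate(lds):
            base = latent if ld.attribute == "+" else (2.0 * offset - latent)
            vals = ld.loading * base
            if ld.noise_sd > 0:
                vals = vals + rng.normal(0.0, ld.noise_sd, size=vals.shape)
            X[:, :, k] = np.clip(vals, sim.POSITIVITY_EPS, None)
            attrs.append(ld.attribute)
        for t in range(T):
            scores, _, _ = score_cross_section(X[:, t, :], attrs)
            Y[:, t, s_idx] = scores
    return Y


def granger_rejection_rates(regime: str, n_reps: int = 500, seed: int = 0,
                            n_units: int = 31, n_periods: int = 10,
                            p: int = 2, alpha: float = 0.05,
                            method: str = "fod_iv"
                            ) -> dict[tuple[str, str], float]:
    """Share of replicates rejecting each Granger null under ``regime``.

    Each replicate runs simulation -> scoring -> panel VAR -> Granger at
    level ``alpha``; returns {(cause, effect): rejection rate}.
    """
    base = sim.preset_regimes(regime, n_units=n_units, n_periods=n_periods)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    counts: dict[tuple[str, str], int] = {}
    for r in range(n_reps):
        spec = replace(base, seed=int(rep_seeds[r]))
        Y = scored_array(spec)
        model = pv.fit_panel_var(Y, p=p, method=method)
        res = pv.granger(model, alpha=alpha).to_frame()
        for _, row in res.iterrows():
            key = (row["cause"], row["effect"])
            counts[key] = counts.get(key, 0) + int(row["reject"])
    return {k: v / n_reps for k, v in counts.items()}


def coefficient_means(regime: str, n_reps: int = 200, seed: int = 0,
                      n_units: int = 31, n_periods: int = 50, p: int = 2,
                      method: str = "fod_iv", use_latent: bool = True
                      ) -> np.ndarray:
    """Mean estimated lag matrices over replicates, shape (p, 2, 2).

    With ``use_latent=True`` the estimator sees the latent scores
    themselves, so the means are directly comparable with the regime's
    true A matrices (entropy scoring rescales the series and hence the
    coefficients' units).
    """
    base = sim.preset_regimes(regime, n_units=n_units, n_periods=n_periods)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=n_reps)
    acc = np.zeros((p, 2, 2))
    for r in range(n_reps):
        spec = replace(base, seed=int(rep_seeds[r]))
        if use_latent:
            Y = sim.simulate_latent(spec).latent
        else:
            Y = scored_array(spec)
        model = pv.fit_panel_var(Y, p=p, method=method)
        acc += model.A
    return acc / n_reps
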