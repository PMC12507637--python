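"""End-to-end pipeline: scoring -> stationarity -> PVAR -> coupling.

`run_pipeline` chains the four analysis stages on one indicator panel and
writes every result table (plus a run manifest) as plain CSV to the output
directory.  All randomness (only the IRF bootstrap uses any) flows from
one root seed, split per stage, so stages are independently reproducible
and a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import coupling as coupling_mod
from . import entropy, io, pvar
from .indexspec import IndexSpec, default_index_spec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "summarize_by_group"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the four-stage pipeline, with the published defaults.

    Defaults follow the study design: 0.01 normalisation floor, per-year
    weighting, ADF at the 5% level with a strict-majority rule, lag order
    chosen by AIC/BIC/HQIC consensus (capped at ``max_lag``), equal
    coordination weights alpha = beta = 0.5, ten-level D bins and
    0.9 / 1.1 relative-development thresholds.
    """

    panel_path: str | Path = ""
    index_spec_path: str | Path | None = None
    out_dir: str | Path = "out"
    normalization: str = "year"
    adf_alpha: float = 0.05
    majority_threshold: float = 0.5
    max_lag: int = 4
    lag_order: int | None = None       # None -> information-criterion consensus
    estimator: str = "fod_iv"
    granger_alpha: float = 0.05
    irf_horizon: int = 10
    n_boot: int = 200
    coord_alpha: float = 0.5
    coord_beta: float = 0.5
    ordering: tuple[str, str] = ("VHR", "PAAW")
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["panel_path"] = str(d["panel_path"])
        d["out_dir"] = str(d["out_dir"])
        if d["index_spec_path"] is not None:
            d["index_spec_path"] = str(d["index_spec_path"])
        d["ordering"] = list(d["ordering"])
        return d


@dataclass
class PipelineResult:
    weights: pd.DataFrame
    scores: pd.DataFrame
    stationarity: pd.DataFrame
    lag_selection: pd.DataFrame
    consensus_lag: int
    model: pvar.PVARModel
    granger: pd.DataFrame
    irf: pd.DataFrame
    coupling: pd.DataFrame
    manifest: dict


def _coef_frame(model: pvar.PVARModel) -> pd.DataFrame:
    rows = []
    k = len(model.subsystems)
    for e_idx, eq in enumerate(model.subsystems):
        for l in range(model.order):
            for v_idx, var in enumerate(model.subsystems):
                j = l * k + v_idx
                rows.append({
                    "equation": eq,
                    "regressor": f"{var} lag {l + 1}",
                    "coef": model.eq_coefs[e_idx, j],
                    "se": float(np.sqrt(model.eq_cov[e_idx][j, j])),
                })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 panel: pd.DataFrame | None = None) -> PipelineResult:
    """Execute scoring, stationarity, PVAR/Granger/IRF and coupling.

    ``panel`` may be passed directly (in-memory use); otherwise it is read
    from ``config.panel_path``.  Any stage failure aborts with the stage
    name attached.  Output tables are written to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    # one child per stage so stages can be rerun in isolation
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(
                       ("score", "stationarity", "pvar", "irf", "coupling"),
                       seed_seq.spawn(5))}

    if panel is None:
        if not Path(config.panel_path).exists():
            raise FileNotFoundError(
                f"stage 'load': panel file not found: {config.panel_path}")
        panel = io.read_panel(config.panel_path)
    if config.index_spec_path is not None:
        spec = IndexSpec.from_yaml(config.index_spec_path)
    else:
        spec = None

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    weights, scores = _stage(
        "score", entropy.score_panel, panel, index_spec=spec,
        normalization=config.normalization)

    summary = _stage(
        "stationarity", pvar.panel_stationarity, scores,
        alpha=config.adf_alpha, majority_threshold=config.majority_threshold,
        order=config.ordering)
    for sub, ok in summary.verdicts.items():
        if not ok:
            logger.warning(
                "subsystem %s fails the majority stationarity rule "
                "(%.1f%% stationary); PVAR estimates may be spurious",
                sub, summary.proportions[sub])

    lag_sel = _stage("lag-selection", pvar.select_lag, scores,
                     max_p=config.max_lag, order=config.ordering)
    p = config.lag_order or lag_sel.consensus

    model = _stage("pvar", pvar.fit_pvar, scores, p=p,
                   method=config.estimator, order=config.ordering)
    granger_res = _stage("granger", pvar.granger, model,
                         alpha=config.granger_alpha)
    irf_res = _stage("irf", pvar.impulse_response, model,
                     horizon=config.irf_horizon, ordering=config.ordering,
                     n_boot=config.n_boot, seed=stage_seeds["irf"])

    coupling_table = _stage(
        "coupling", coupling_mod.coupling_panel, scores,
        alpha=config.coord_alpha, beta=config.coord_beta,
        subsystems=config.ordering)

    manifest = {
        "package": "vetcoord",
        "version": __version__,
        "config": config.to_jsonable(),
        "stage_seeds": stage_seeds,
        "consensus_lag": lag_sel.consensus,
        "lag_order_used": p,
        "rows": {
            "panel": int(len(panel)),
            "weights": int(len(weights)),
            "scores": int(len(scores)),
            "coupling": int(len(coupling_table)),
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    io.write_table(weights, out / "weights.csv")
    io.write_scores(scores, out / "scores.csv")
    io.write_table(summary.to_frame(), out / "stationarity.csv")
    io.write_table(lag_sel.to_frame(), out / "lag_selection.csv")
    io.write_table(_coef_frame(model), out / "pvar_coefficients.csv")
    io.write_table(granger_res.to_frame(), out / "granger.csv")
    io.write_table(irf_res.to_frame(), out / "irf.csv")
    io.write_table(coupling_table, out / "coupling.csv")
    coupling_mod.wide_matrix(coupling_table, "D").to_csv(out / "D_matrix.csv")
    coupling_mod.wide_matrix(coupling_table, "dev_type").to_csv(
        out / "dev_type_matrix.csv")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")

    return PipelineResult(
        weights=weights, scores=scores, stationarity=summary.to_frame(),
        lag_selection=lag_sel.to_frame(), consensus_lag=lag_sel.consensus,
        model=model, granger=granger_res.to_frame(), irf=irf_res.to_frame(),
        coupling=coupling_table, manifest=manifest)


def summarize_by_group(table: pd.DataFrame,
                       grouping: Mapping[str, str],
                       value_cols: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Unweighted group-by-year means of score/coupling columns.

    Presentational only (mirrors the six-region regional averages used
    for visualisation); analyses stay at the unit level.  Every unit must
    be mapped to exactly one group.
    """
    units = set(table["unit"].unique())
    unmapped = sorted(units - set(grouping))
    if unmapped:
        raise ValueError(f"units not present in grouping map: {unmapped}")
    if value_cols is None:
        candidates = ("score", "U_V", "U_A", "C", "T_index", "D", "R")
        value_cols = [c for c in candidates if c in table.columns]
        if not value_cols:
            raise ValueError("no numeric value columns found to summarise")
    df = table.copy()
    df["group"] = df["unit"].map(grouping)
    keys = ["group", "year"]
    if "subsystem" in df.columns:
        keys.insert(1, "subsystem")
    out = df.groupby(keys, sort=True)[list(value_cols)].mean().reset_index()
    out.attrs["note"] = "presentational grouping; analyses are unit-level"
    return out
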