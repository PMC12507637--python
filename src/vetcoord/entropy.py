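"""Entropy-weight composite scoring of an indicator panel.

For every (year, subsystem) cross-section the pipeline

1. min–max normalises each indicator across units (benefit indicators by
   (x - min)/(max - min), cost indicators mirrored), replacing exact
   zeros by a 0.01 floor so every unit contributes minimally;
2. converts each indicator's normalised column to proportions
   P[u] = Y[u] / sum_u Y[u] and computes its Shannon entropy
   e = -(1/ln n_units) * sum_u P[u] ln P[u];
3. weights each indicator by its information content,
   w = (1 - e) / sum_j (1 - e_j);
4. scores each unit as the weighted sum of its normalised values.

Weights are computed separately for each year so that shifts in the
cross-sectional distribution over time cannot leak across periods.  A
constant (zero-variance) indicator carries no discriminating information:
it is floored to 0.01, assigned entropy 1 and hence weight 0, with a
logged warning.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FLOOR = 0.01

logger = logging.getLogger(__name__)

__all__ = [
    "minmax_normalize",
    "entropy_weights",
    "composite_scores",
    "normalize_slice",
    "score_panel",
]


# ---------------------------------------------------------------------------
# array core (units x indicators), used directly by the Monte-Carlo loops
# ---------------------------------------------------------------------------

def minmax_normalize(X: np.ndarray, attributes: Sequence[str],
                     floor: float = FLOOR) -> np.ndarray:
    """Min–max normalise one cross-section, column per indicator.

    Constant columns (max == min) are set to the floor value and warned
    about; they receive zero weight downstream.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (units x indicators) array")
    if not np.isfinite(X).all():
        raise ValueError("indicator values must be finite")
    if len(attributes) != X.shape[1]:
        raise ValueError("one attribute sign required per indicator column")

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)

    Y = np.empty_like(X)
    for j, attr in enumerate(attributes):
        if attr == "+":
            Y[:, j] = (X[:, j] - lo[j]) / span_safe[j]
        elif attr == "-":
            Y[:, j] = (hi[j] - X[:, j]) / span_safe[j]
        else:
            raise ValueError(f"attribute must be '+' or '-', got {attr!r}")
    if constant.any():
        logger.warning(
            "constant indicator column(s) %s normalised to the %.2f floor "
            "(zero weight downstream)", np.where(constant)[0].tolist(), floor)
        Y[:, constant] = floor
    # floor applies to exact zeros only, per the published rule
    Y[Y == 0.0] = floor
    return Y


def entropy_weights(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Entropy and weight per indicator from a normalised cross-section.

    Returns ``(weights, entropies)``.  Requires all values > 0 (the floor
    guarantees this).  If every indicator is constant (all entropies 1),
    falls back to equal weights with a logged warning.
    """
    Y = np.asarray(Y, dtype=float)
    n_units, n_ind = Y.shape
    if (Y <= 0).any():
        raise ValueError("normalised values must be strictly positive")
    if n_units < 2:
        raise ValueError("entropy weighting needs at least 2 units")

    P = Y / Y.sum(axis=0, keepdims=True)
    e = -(P * np.log(P)).sum(axis=0) / np.log(n_units)
    # guard tiny negative / >1 excursions from floating point
    e = np.clip(e, 0.0, 1.0)
    info = 1.0 - e
    total = info.sum()
    if total <= 0:
        logger.warning(
            "all indicators are non-informative (entropy 1); "
            "falling back to equal weights")
        w = np.full(n_ind, 1.0 / n_ind)
    else:
        w = info / total
    return w, e


def composite_scores(Y: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted-sum score per unit; stays within [floor, 1]."""
    Y = np.asarray(Y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if Y.shape[1] != weights.shape[0]:
        raise ValueError(
            f"{Y.shape[1]} indicator columns but {weights.shape[0]} weights")
    return Y @ weights


def score_cross_section(X: np.ndarray, attributes: Sequence[str],
                        floor: float = FLOOR
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """normalise -> entropy weights -> scores for one (year, subsystem)."""
    Y = minmax_normalize(X, attributes, floor)
    w, e = entropy_weights(Y)
    return composite_scores(Y, w), w, e


# ---------------------------------------------------------------------------
# DataFrame surface
# ---------------------------------------------------------------------------

def _pivot_slice(slice_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a one-(year, subsystem) slice to units x indicators, checking
    balance."""
    wide = slice_df.pivot_table(index="unit", columns="indicator",
                                values="value", aggfunc="first", sort=True)
    if wide.isna().any().any():
        gaps = [
            (u, i)
            for u in wide.index
            for i in wide.columns
            if pd.isna(wide.loc[u, i])
        ]
        raise ValueError(f"unbalanced slice; missing (unit, indicator): {gaps}")
    return wide


def normalize_slice(slice_df: pd.DataFrame,
                    attributes: Mapping[str, str] | None = None,
                    floor: float = FLOOR) -> pd.DataFrame:
    """Normalise one (year, subsystem) slice given indicator attributes.

    ``slice_df`` is long format with columns unit, indicator, value;
    missing attributes default to benefit-type ("+").
    """
    wide = _pivot_slice(slice_df)
    attrs = [
        (attributes or {}).get(ind, "+") for ind in wide.columns
    ]
    Y = minmax_normalize(wide.to_numpy(), attrs, floor)
    return pd.DataFrame(Y, index=wide.index, columns=wide.columns)


def score_panel(panel: pd.DataFrame,
                index_spec=None,
                normalization: str = "year",
                floor: float = FLOOR
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a full long-format indicator panel.

    Parameters
    ----------
    panel
        Long table with columns unit, year, subsystem, indicator, value.
    index_spec
        Optional :class:`~vetcoord.indexspec.IndexSpec` supplying the
        attribute sign of each indicator; indicators absent from the spec
        default to "+".
    normalization
        ``"year"`` (default): min–max within each (year, subsystem)
        cross-section, matching the per-year weighting.  ``"pooled"``:
        min and max taken over all years of a subsystem's indicator;
        entropy and weights are still computed per year.  Pooling changes
        cross-year comparability and is off by default.

    Returns
    -------
    (weights, scores)
        ``weights``: year, subsystem, indicator, weight, entropy.
        ``scores``: unit, year, subsystem, score.
    """
    required = {"unit", "year", "subsystem", "indicator", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if normalization not in ("year", "pooled"):
        raise ValueError("normalization must be 'year' or 'pooled'")

    attr_map: dict[str, str] = {}
    if index_spec is not None:
        for sub in index_spec.subsystem_names:
            attr_map.update(index_spec.attributes(sub))

    pooled_bounds: dict[tuple[str, str], tuple[float, float]] = {}
    if normalization == "pooled":
        g = panel.groupby(["subsystem", "indicator"])["value"]
        for key, (lo, hi) in g.agg(["min", "max"]).iterrows():
            pooled_bounds[key] = (lo, hi)

    weight_rows = []
    score_rows = []
    for (year, sub), slice_df in panel.groupby(["year", "subsystem"],
                                               sort=True):
        try:
            wide = _pivot_slice(slice_df)
        except ValueError as err:
            raise ValueError(f"(year={year}, subsystem={sub}): {err}") from None
        attrs = [attr_map.get(ind, "+") for ind in wide.columns]
        X = wide.to_numpy()
        if normalization == "pooled":
            Y = np.empty_like(X, dtype=float)
            for j, ind in enumerate(wide.columns):
                lo, hi = pooled_bounds[(sub, ind)]
                span = hi - lo
                if span == 0:
                    Y[:, j] = floor
                    continue
                if attrs[j] == "+":
                    Y[:, j] = (X[:, j] - lo) / span
                else:
                    Y[:, j] = (hi - X[:, j]) / span
            Y[Y == 0.0] = floor
        else:
            Y = minmax_normalize(X, attrs, floor)
        w, e = entropy_weights(Y)
        scores = composite_scores(Y, w)
        for ind, wj, ej in zip(wide.columns, w, e):
            weight_rows.append((year, sub, ind, wj, ej))
        for unit, s in zip(wide.index, scores):
            score_rows.append((unit, year, sub, s))

    weights = pd.DataFrame(
        weight_rows, columns=["year", "subsystem", "indicator", "weight",
                              "entropy"])
    scores = pd.DataFrame(
        score_rows, columns=["unit", "year", "subsystem", "score"]
    ).sort_values(["unit", "year", "subsystem"], ignore_index=True)
    return weights, scores
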