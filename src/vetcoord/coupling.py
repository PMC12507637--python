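"""Coupling degree, coupling coordination degree and relative development.

Given the two composite subsystem scores U_V (veterinary workforce, VHR)
and U_A (public attention, PAAW) of a province-year:

    C = 2 * sqrt( U_V * U_A / (U_V + U_A)^2 )      coupling degree
    T = alpha * U_V + beta * U_A                   coordination index
    D = sqrt(C * T)                                coupling coordination degree
    R = U_V / U_A                                  relative development degree

C measures balance only (C = 1 whenever the two scores are equal, even at
low levels); D folds in the joint level T, so balanced-but-low systems are
still classified as uncoordinated.  D is binned into ten coordination
levels; R into three development types (VHR lag / synchronised / PAAW lag).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COORDINATION_LEVELS",
    "DEVELOPMENT_TYPES",
    "coupling_degree",
    "coordination_index",
    "ccd",
    "classify_coordination",
    "relative_development",
    "classify_development",
    "coupling_panel",
]

#: Ten-level classification of D: half-open deciles, closed top bin.
COORDINATION_LEVELS = (
    "Extremely uncoordinated",   # 0.0 <= D < 0.1
    "Severely uncoordinated",    # 0.1 <= D < 0.2
    "Moderately uncoordinated",  # 0.2 <= D < 0.3
    "Slightly uncoordinated",    # 0.3 <= D < 0.4
    "Nearly uncoordinated",      # 0.4 <= D < 0.5
    "Barely coordinated",        # 0.5 <= D < 0.6
    "Primarily coordinated",     # 0.6 <= D < 0.7
    "Moderately coordinated",    # 0.7 <= D < 0.8
    "Well coordinated",          # 0.8 <= D < 0.9
    "Perfectly coordinated",     # 0.9 <= D <= 1.0
)

DEVELOPMENT_TYPES = ("VHR lag", "VHR-PAAW synchronization", "PAAW lag")

#: R thresholds: R < 0.9 -> VHR lag; 0.9 <= R <= 1.1 -> synchronization;
#: R > 1.1 -> PAAW lag (both bounds closed for synchronization).
RDD_LOW, RDD_HIGH = 0.9, 1.1


def coupling_degree(u_v, u_a):
    """C = 2*sqrt(U_V*U_A/(U_V+U_A)^2); defined as 0 when both are 0."""
    u_v = np.asarray(u_v, dtype=float)
    u_a = np.asarray(u_a, dtype=float)
    if (u_v < 0).any() or (u_a < 0).any():
        raise ValueError("subsystem scores must be non-negative")
    total = u_v + u_a
    safe = np.where(total == 0, 1.0, total)
    c = 2.0 * np.sqrt(u_v * u_a) / safe
    c = np.where(total == 0, 0.0, c)
    # clamp float error so parity gives exactly 1
    c = np.minimum(c, 1.0)
    return c if c.ndim else float(c)


def coordination_index(u_v, u_a, alpha: float = 0.5, beta: float = 0.5):
    """T = alpha*U_V + beta*U_A with alpha + beta = 1 (defaults 0.5/0.5)."""
    if alpha < 0 or beta < 0 or abs(alpha + beta - 1.0) > 1e-12:
        raise ValueError(
            f"alpha and beta must be non-negative and sum to 1 "
            f"(got {alpha}, {beta})")
    t = alpha * np.asarray(u_v, dtype=float) + beta * np.asarray(u_a, dtype=float)
    return t if t.ndim else float(t)


def ccd(c, t_index):
    """D = sqrt(C * T); inputs must lie in [0, 1]."""
    c = np.asarray(c, dtype=float)
    t_index = np.asarray(t_index, dtype=float)
    if ((c < 0) | (c > 1)).any() or ((t_index < 0) | (t_index > 1)).any():
        raise ValueError("C and T must lie in [0, 1]")
    d = np.sqrt(c * t_index)
    return d if d.ndim else float(d)


def classify_coordination(d):
    """Map D in [0, 1] to its ten-level coordination label."""
    arr = np.asarray(d, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"D must lie in [0, 1], got {d}")
    edges = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    idx = np.digitize(arr, edges, right=False)  # closed top bin via <= 1 check
    labels = np.asarray(COORDINATION_LEVELS, dtype=object)[idx]
    return labels if arr.ndim else str(labels)


def relative_development(u_v, u_a):
    """R = U_V / U_A.  U_A = 0 is an error: the 0.01 scoring floor makes a
    zero score unreachable in-pipeline, so it signals corrupted input."""
    u_v = np.asarray(u_v, dtype=float)
    u_a = np.asarray(u_a, dtype=float)
    if (u_v < 0).any():
        raise ValueError("U_V must be non-negative")
    if (u_a <= 0).any():
        raise ValueError("relative development undefined: U_A must be > 0")
    r = u_v / u_a
    return r if r.ndim else float(r)


def classify_development(r):
    """Three development types from R with closed bounds at 0.9 and 1.1."""
    arr = np.asarray(r, dtype=float)
    if (arr < 0).any():
        raise ValueError("R must be non-negative")
    labels = np.where(
        arr < RDD_LOW, DEVELOPMENT_TYPES[0],
        np.where(arr > RDD_HIGH, DEVELOPMENT_TYPES[2], DEVELOPMENT_TYPES[1]),
    ).astype(object)
    return labels if arr.ndim else str(labels)


def coupling_panel(scores: pd.DataFrame, alpha: float = 0.5,
                   beta: float = 0.5,
                   subsystems: tuple[str, str] = ("VHR", "PAAW")
                   ) -> pd.DataFrame:
    """Apply the full C → T → D → level, R → type chain per (unit, year).

    ``scores`` is the long score panel (unit, year, subsystem, score) and
    must contain both subsystems for every (unit, year).  Output is sorted
    by unit then year with columns unit, year, U_V, U_A, C, T_index, D,
    level, R, dev_type.
    """
    sub_v, sub_a = subsystems
    wide = scores.pivot_table(index=["unit", "year"], columns="subsystem",
                              values="score", aggfunc="first")
    for sub in subsystems:
        if sub not in wide.columns:
            raise ValueError(f"score panel has no subsystem {sub!r}")
    gaps = wide.index[wide[[sub_v, sub_a]].isna().any(axis=1)].tolist()
    if gaps:
        raise ValueError(
            f"missing subsystem score for (unit, year) pairs: {gaps}")

    u_v = wide[sub_v].to_numpy()
    u_a = wide[sub_a].to_numpy()
    c = coupling_degree(u_v, u_a)
    t = coordination_index(u_v, u_a, alpha, beta)
    d = ccd(c, t)
    r = relative_development(u_v, u_a)

    out = pd.DataFrame(
        {
            "unit": wide.index.get_level_values("unit"),
            "year": wide.index.get_level_values("year"),
            "U_V": u_v,
            "U_A": u_a,
            "C": c,
            "T_index": t,
            "D": d,
            "level": classify_coordination(d),
            "R": r,
            "dev_type": classify_development(r),
        }
    )
    return out.sort_values(["unit", "year"], ignore_index=True)


def wide_matrix(coupling_table: pd.DataFrame, column: str = "D"
                ) -> pd.DataFrame:
    """Year x unit matrix of one coupling column, for heatmaps/choropleths."""
    return coupling_table.pivot_table(index="year", columns="unit",
                                      values=column, aggfunc="first",
                                      sort=True)
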