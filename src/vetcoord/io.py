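"""Reading and writing the package's plain-text table formats.

Everything is UTF-8 comma-separated text with a header row.  The two core
shapes are the long indicator panel (unit, year, subsystem, indicator,
value) and the long score panel (unit, year, subsystem, score).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PANEL_COLUMNS = ["unit", "year", "subsystem", "indicator", "value"]
SCORE_COLUMNS = ["unit", "year", "subsystem", "score"]
WEIGHT_COLUMNS = ["year", "subsystem", "indicator", "weight", "entropy"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read a long-format indicator panel."""
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, f"panel file {path}")
    if not df["value"].map(lambda v: pd.notna(v)).all():
        raise ValueError(f"panel file {path} contains missing values")
    return df[PANEL_COLUMNS]


def write_panel(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, PANEL_COLUMNS, "panel")
    df[PANEL_COLUMNS].to_csv(path, index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SCORE_COLUMNS, f"score file {path}")
    return df[SCORE_COLUMNS]


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, SCORE_COLUMNS, "score table")
    df[SCORE_COLUMNS].to_csv(path, index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as CSV without the index."""
    df.to_csv(path, index=False)
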