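"""Reading and writing the package's CSV formats.

Survey tables use the canonical schema (comma-separated, UTF-8, header
row, lowercase category tokens)::

    pond,year,window,method,observer,time_min,detected

``detected`` is serialised as 0/1.  Grid results are written both as a
wide Fig-style table (rows = bellwether count, columns = correlation,
cells = "mean (sd)") and as a tidy long table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulator import GridResult
from .survival import CANONICAL_LEVELS, CENSOR_MINUTES

__all__ = ["read_survey_csv", "write_survey_csv", "write_grid_csv"]

SURVEY_COLUMNS = ["pond", "year", "window", "method", "observer", "time_min", "detected"]


class SurveyValidationError(ValueError):
    """Survey CSV fails schema or range validation."""


def _validate_surveys(df: pd.DataFrame, source: str) -> pd.DataFrame:
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["time_min"] <= 0 or row["time_min"] > CENSOR_MINUTES:
            problems.append(
                f"{source}:{rowno}: time_min {row['time_min']} outside (0, {CENSOR_MINUTES:g}]"
            )
        if not row["detected"] and row["time_min"] != CENSOR_MINUTES:
            problems.append(
                f"{source}:{rowno}: censored record must have time_min = {CENSOR_MINUTES:g}"
            )
        for var in ("window", "method"):
            if str(row[var]) not in CANONICAL_LEVELS[var]:
                problems.append(
                    f"{source}:{rowno}: unknown {var} category {row[var]!r}"
                )
    if problems:
        raise SurveyValidationError("\n".join(problems))
    return df


def read_survey_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict_categories: bool = True,
) -> pd.DataFrame:
    """Read and validate a survey table.

    Parameters
    ----------
    path : path to a CSV file with the canonical header.
    column_map : optional mapping from the file's column names to the
        canonical ones, for tables using a different header.
    strict_categories : reject window/method tokens outside the
        canonical vocabulary (disable for free-form category sets).

    Raises
    ------
    SurveyValidationError
        On missing columns, unparseable fields, out-of-range times, or
        (when strict) unknown categories — with row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyValidationError(
            f"{path.name}: missing column(s) {sorted(missing)}; "
            f"expected header {SURVEY_COLUMNS}"
        )
    df = df[SURVEY_COLUMNS].copy()
    try:
        df["time_min"] = df["time_min"].astype(float)
        df["year"] = df["year"].astype(int)
        df["detected"] = df["detected"].astype(int).astype(bool)
    except (ValueError, TypeError) as exc:
        raise SurveyValidationError(f"{path.name}: unparseable field: {exc}") from exc
    for var in ("pond", "window", "method", "observer"):
        df[var] = df[var].astype(str)
    if strict_categories:
        _validate_surveys(df, path.name)
    return df


def write_survey_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a survey table in the canonical schema (0/1 detected flag)."""
    out = df[SURVEY_COLUMNS].copy()
    out["detected"] = out["detected"].astype(int)
    out.to_csv(path, index=False)


def grid_to_frames(grid: GridResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide "mean (sd)" table and tidy long table for a grid result."""
    if not (np.all(np.isfinite(grid.mean)) and np.all(np.isfinite(grid.sd))):
        raise ValueError("grid contains non-finite cells; refusing to write")
    wide = pd.DataFrame(
        [
            [f"{m:.1f} ({s:.2f})" for m, s in zip(mrow, srow)]
            for mrow, srow in zip(grid.mean, grid.sd)
        ],
        index=pd.Index(grid.bellwether_counts, name="n_bellwether"),
        columns=[f"{c:g}" for c in grid.correlations],
    )
    long = pd.DataFrame(
        {
            "n_bellwether": np.repeat(grid.bellwether_counts, len(grid.correlations)),
            "correlation": np.tile(grid.correlations, len(grid.bellwether_counts)),
            "mean_detections": grid.mean.ravel(),
            "sd_detections": grid.sd.ravel(),
        }
    )
    return wide, long


def write_grid_csv(grid: GridResult, path: str | Path) -> Path:
    """Write the wide grid table to ``path`` and the tidy long table to
    ``<path stem>_long.csv``; returns the long-table path.

    Formatting is deterministic (mean to 1 decimal, sd to 2), so
    re-running with the same seed reproduces the files byte-for-byte.
    """
    path = Path(path)
    wide, long = grid_to_frames(grid)
    wide.to_csv(path)
    long_path = path.with_name(path.stem + "_long.csv")
    long.to_csv(long_path, index=False, float_format="%.6g")
    return long_path
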