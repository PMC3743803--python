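"""Cause-specific death fractions from regional cause-count tables.

A cause-specific fraction (CSF) is the share of a region's deaths assigned
to one broad ICD-10 chapter group, as a percentage of all registered deaths
in that region.  Top-five tables are partial partitions, so per-region CSFs
need not sum to 100%.  Cause labels are opaque strings; no ICD parsing is
attempted.  The package bundles the South Africa 2007 provincial top-five
tabulation from vital registration as a worked-example dataset.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "csf",
    "csf_table",
    "rank_causes",
    "correlate",
    "read_cause_counts",
    "load_example_cause_counts",
]

CAUSE_COLUMNS = ["region_id", "cause", "cause_count", "total_deaths"]


def csf(cause_count: int, total: int) -> float:
    """Cause-specific fraction as a percentage, at full precision."""
    if total <= 0:
        raise UndefinedStatisticError("total deaths must be positive")
    if cause_count < 0 or cause_count > total:
        raise ParameterError(f"cause count {cause_count} outside [0, {total}]")
    return 100.0 * cause_count / total


def read_cause_counts(path: str | Path) -> pd.DataFrame:
    """Read a cause-count CSV (region_id, cause, cause_count, total_deaths)."""
    table = pd.read_csv(path)
    missing = set(CAUSE_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"cause-count table missing columns {sorted(missing)}")
    _validate(table)
    return table


def load_example_cause_counts() -> pd.DataFrame:
    """Bundled South Africa 2007 provincial top-five cause tabulation."""
    with resources.files("mortframe.data").joinpath("za2007_cause_counts.csv").open() as fh:
        return read_cause_counts(fh)


def _validate(table: pd.DataFrame) -> None:
    if (table["total_deaths"] <= 0).any():
        raise UndefinedStatisticError("total deaths must be positive in every row")
    if ((table["cause_count"] < 0) | (table["cause_count"] > table["total_deaths"])).any():
        raise ParameterError("cause count outside [0, total] in some row")
    partial_sums = table.groupby("region_id")["cause_count"].sum()
    totals = table.groupby("region_id")["total_deaths"].first()
    if (partial_sums > totals).any():
        raise ParameterError("cause counts exceed total deaths within a region")


def csf_table(table: pd.DataFrame, decimals: int | None = 2) -> pd.DataFrame:
    """Append a ``csf`` percentage column; rounding applies at report time only."""
    _validate(table)
    out = table.copy()
    out["csf"] = 100.0 * out["cause_count"] / out["total_deaths"]
    if decimals is not None:
        out["csf"] = out["csf"].round(decimals)
    return out


def rank_causes(region_rows: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k causes of one region by descending CSF; ties break by cause label."""
    if k < 1:
        raise ParameterError("k must be at least 1")
    ranked = csf_table(region_rows, decimals=None).sort_values(
        ["csf", "cause"], ascending=[False, True], ignore_index=True
    )
    return ranked.head(k)


def correlate(series_a, series_b) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    Used to relate regional cause-specific fractions (e.g. infectious
    causes) to all-cause mortality estimates across regions.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ParameterError("need at least 3 paired regional values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("non-finite values in correlation input")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue)
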