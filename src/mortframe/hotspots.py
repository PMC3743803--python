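"""Unit-level mortality summaries and hotspot classification.

A "hotspot" is an areal unit whose mortality proportion is significantly
above the national average: the lower limit of the exact (Clopper-Pearson)
two-sided 95% binomial confidence interval — a one-sided tail probability
of 0.025 — must strictly exceed the national average proportion.  The
national average is treated as a fixed reference constant, and the unit's
own deaths are not excluded from it.  Standardised mortality ratios compare
observed deaths with the count expected if the national rate applied to the
unit's population.

No multiple-testing correction is applied by default (the number of tests
is surfaced to the caller); Bonferroni and Benjamini-Hochberg switches are
available via ``correction=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "ArealUnit",
    "PER_10K",
    "mortality_proportion",
    "exact_binomial_ci",
    "expected_deaths",
    "smr",
    "classify_hotspots",
    "aggregate_persons",
    "national_proportion",
]

PER_10K = 10_000.0

SUMMARY_COLUMNS = [
    "unit_id", "level", "parent_id", "deaths", "population",
    "proportion", "ci_low", "ci_high", "expected_deaths", "smr", "hotspot",
]


@dataclass(frozen=True)
class ArealUnit:
    """One node of the national/province/district/municipality hierarchy."""

    unit_id: str
    level: str
    parent_id: str | None
    deaths: int
    population: int

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise UndefinedStatisticError(
                f"unit {self.unit_id}: population must be positive"
            )
        if not 0 <= self.deaths <= self.population:
            raise ParameterError(
                f"unit {self.unit_id}: deaths {self.deaths} outside [0, population]"
            )


def mortality_proportion(deaths: int, population: int) -> float:
    """Deaths per 10,000 population."""
    if population <= 0:
        raise UndefinedStatisticError("population must be positive")
    if deaths < 0 or deaths > population:
        raise ParameterError(f"deaths {deaths} outside [0, {population}]")
    return PER_10K * deaths / population


def exact_binomial_ci(deaths, population, alpha: float = 0.05):
    """Clopper-Pearson exact two-sided interval for a binomial proportion.

    Returns (low, high) on the probability scale.  The limits are the beta
    quantiles Beta(alpha/2; d, n-d+1) and Beta(1-alpha/2; d+1, n-d), with
    low = 0 at d = 0 and high = 1 at d = n.  Accepts scalars or arrays.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha {alpha} outside (0, 1)")
    d = np.asarray(deaths)
    n = np.asarray(population)
    if np.any(d < 0) or np.any(d > n):
        raise ParameterError("deaths outside [0, population]")
    with np.errstate(invalid="ignore"):
        low = np.where(d == 0, 0.0, stats.beta.ppf(alpha / 2.0, d, n - d + 1))
        high = np.where(d == n, 1.0, stats.beta.ppf(1.0 - alpha / 2.0, d + 1, n - d))
    if np.isscalar(deaths) or d.ndim == 0:
        return float(low), float(high)
    return low, high


def expected_deaths(population: int, national_prop: float) -> float:
    """Deaths expected if the national average rate applied to this unit."""
    if not 0.0 <= national_prop <= 1.0:
        raise ParameterError(f"national proportion {national_prop} outside [0, 1]")
    return population * national_prop


def smr(observed: int, expected: float) -> float:
    """Standardised mortality ratio: observed / expected deaths."""
    if expected <= 0:
        raise UndefinedStatisticError("expected deaths must be positive for an SMR")
    return observed / expected


def national_proportion(units: pd.DataFrame) -> float:
    """Pooled national death probability from municipality-level rows."""
    munis = units[units["level"] == "municipality"] if "level" in units else units
    total_pop = munis["population"].sum()
    if total_pop <= 0:
        raise UndefinedStatisticError("no population in unit table")
    return float(munis["deaths"].sum() / total_pop)


def aggregate_persons(persons: pd.DataFrame, denominator: str = "respondents") -> pd.DataFrame:
    """Roll person records up to unit rows at all four hierarchy levels.

    ``denominator`` selects what stands in for the unit population:
    ``"respondents"`` (all enumerated persons, the default) or
    ``"midyear"`` (respondents minus half the deaths, a mid-period
    approximation for rate-style denominators).
    """
    if denominator not in ("respondents", "midyear"):
        raise ParameterError(f"unknown denominator {denominator!r}")

    def _pop(n_persons: pd.Series, deaths: pd.Series) -> pd.Series:
        if denominator == "respondents":
            return n_persons
        return (n_persons - deaths / 2.0).round().astype(int)

    frames = []
    specs = [
        ("municipality", "municipality_id", "district_id"),
        ("district", "district_id", "province_id"),
        ("province", "province_id", None),
    ]
    for level, key, parent_key in specs:
        grp = persons.groupby(key, sort=True)
        agg = grp.agg(deaths=("died", "sum"), n=("died", "size"))
        if parent_key is not None:
            agg["parent_id"] = grp[parent_key].first()
        else:
            agg["parent_id"] = "ZA"
        agg = agg.reset_index().rename(columns={key: "unit_id"})
        agg["level"] = level
        agg["population"] = _pop(agg["n"], agg["deaths"])
        frames.append(agg[["unit_id", "level", "parent_id", "deaths", "population"]])
    total_deaths = int(persons["died"].sum())
    total_n = len(persons)
    frames.append(pd.DataFrame([{
        "unit_id": "ZA", "level": "national", "parent_id": None,
        "deaths": total_deaths,
        "population": int(_pop(pd.Series([total_n]), pd.Series([total_deaths])).iloc[0]),
    }]))
    return pd.concat(frames, ignore_index=True)


def classify_hotspots(
    units: pd.DataFrame,
    national_prop: float,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Summarise each unit and flag those significantly above average.

    ``units`` needs columns unit_id, deaths, population (level/parent_id are
    carried through if present).  A unit is a hotspot when the lower limit
    of its two-sided (1-alpha) Clopper-Pearson interval strictly exceeds
    ``national_prop``.  Boundary equality is not a hotspot.

    ``correction`` in {None, "bonferroni", "bh"} optionally adjusts for the
    number of units tested, using the duality between the interval rule and
    the one-sided exact binomial p-value P(X >= d | national_prop).
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha {alpha} outside (0, 1)")
    if not 0.0 <= national_prop <= 1.0:
        raise ParameterError(f"national proportion {national_prop} outside [0, 1]")
    if correction not in (None, "bonferroni", "bh"):
        raise ParameterError(f"unknown correction {correction!r}")
    out = units.copy()
    if out.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    if "level" not in out:
        out["level"] = "municipality"
    if "parent_id" not in out:
        out["parent_id"] = None

    d = out["deaths"].to_numpy()
    n = out["population"].to_numpy()
    if np.any(n <= 0):
        raise UndefinedStatisticError("all units need positive population")
    if np.any((d < 0) | (d > n)):
        raise ParameterError("deaths outside [0, population] in unit table")
    low, high = exact_binomial_ci(d, n, alpha)
    out["proportion"] = PER_10K * d / n
    out["ci_low"] = PER_10K * low
    out["ci_high"] = PER_10K * high
    out["expected_deaths"] = n * national_prop
    out["smr"] = np.where(out["expected_deaths"] > 0, d / out["expected_deaths"], np.nan)

    if correction is None:
        out["hotspot"] = low > national_prop
    else:
        # one-sided exact p: P(X >= d) under the national rate
        pvals = stats.binom.sf(d - 1, n, national_prop)
        m = len(out)
        if correction == "bonferroni":
            out["hotspot"] = pvals < (alpha / 2.0) / m
        else:  # Benjamini-Hochberg step-up at level alpha/2
            order = np.argsort(pvals)
            thresh = (np.arange(1, m + 1) / m) * (alpha / 2.0)
            passed = pvals[order] <= thresh
            k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
            flag = np.zeros(m, dtype=bool)
            flag[order[:k]] = True
            out["hotspot"] = flag
    return out[SUMMARY_COLUMNS]
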