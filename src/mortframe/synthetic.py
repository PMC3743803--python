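"""Synthetic hierarchical survey microdata with planted mortality hotspots.

The generator emulates a household-survey extract over a four-level
administrative hierarchy (national -> province -> district -> local
municipality): each adult aged 15-59 carries a 12-month death indicator and
a set of binary risk-factor exposures.  A configurable fraction of local
municipalities is planted as excess-risk "hotspots" whose death probability
is the baseline multiplied by a known factor, and covariate prevalences
differ between hotspot and non-hotspot units.  The recorded truth object
(planted unit ids, per-unit rates, effect sizes) makes every downstream
stage testable without any confidential survey data.

Randomness is organised as one global seed feeding deterministic
``numpy.random.SeedSequence`` substreams: one stream for hotspot planting,
one per district and one per municipality, so enlarging the hierarchy never
perturbs draws for existing units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "DEFAULT_COVARIATES",
    "generate_hierarchy",
    "generate_persons",
    "generate_unit_counts",
    "simulate_risk_model",
    "implied_marginal_rr",
]

LEVELS = ("national", "province", "district", "municipality")

PERSON_COLUMNS = ("person_id", "municipality_id", "district_id", "province_id", "died")


@dataclass(frozen=True)
class CovariateSpec:
    """One binary exposure: where it lives and how it differs by hotspot status.

    ``level`` is one of individual, household, municipality, district.
    Household exposures are drawn per person (the generator does not build
    household rosters; a household attribute is simply broadcast to its
    members, who here are single rows).  Municipality- and district-level
    exposures are drawn once per areal unit and broadcast.

    ``log_rr`` records the nominal effect size the scenario was designed
    around; it is carried into the truth object for recovery tests.
    """

    name: str
    level: str = "individual"
    prevalence_in_hotspots: float = 0.5
    prevalence_elsewhere: float = 0.5
    log_rr: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in ("individual", "household", "municipality", "district"):
            raise ConfigurationError(f"unknown covariate level {self.level!r}")
        for p in (self.prevalence_in_hotspots, self.prevalence_elsewhere):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: prevalence {p} outside [0, 1]"
                )


#: Default exposure scenario: names, adjusted risk ratios and overall
#: prevalences follow the South-African worked example (male gender 1.13 at
#: 0.52, not-in-formal-union 1.40 at 0.62, low SES 1.70 at 0.39, no basic
#: household service 3.19 at 0.01, district antenatal HIV >=30% 3.98 at
#: 0.42); the hotspot / non-hotspot prevalence splits reconcile those overall
#: prevalences with a 27% hotspot share of the population.
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("male", "individual", 0.530, 0.515, np.log(1.13)),
    CovariateSpec("not_in_union", "individual", 0.710, 0.600, np.log(1.40)),
    CovariateSpec("low_ses", "individual", 0.520, 0.340, np.log(1.70)),
    CovariateSpec("no_basic_service", "household", 0.026, 0.007, np.log(3.19)),
    CovariateSpec("hiv_ge30", "district", 0.650, 0.340, np.log(3.98)),
)


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic survey.

    Defaults reproduce the scale of the motivating national survey: a
    9-province hierarchy disaggregating into ~250 local municipalities,
    ~2,500 sampled adults per municipality, a baseline 12-month death
    probability of 0.0145 (145 per 10,000), 27% of municipalities planted
    as hotspots at 2.2x the baseline rate.
    """

    n_provinces: int = 9
    districts_per_province: int = 6
    municipalities_per_district: int = 5
    persons_per_municipality: int = 2500
    baseline_rate: float = 0.0145
    hotspot_fraction: float = 0.27
    hotspot_rate_multiplier: float = 2.2
    covariates: Sequence[CovariateSpec] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_provinces", "districts_per_province",
                     "municipalities_per_district", "persons_per_municipality"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 <= self.baseline_rate <= 1.0:
            raise ConfigurationError(f"baseline_rate {self.baseline_rate} outside [0, 1]")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ConfigurationError(f"hotspot_fraction {self.hotspot_fraction} outside [0, 1]")
        if self.hotspot_fraction > 0 and self.hotspot_rate_multiplier <= 1.0:
            raise ConfigurationError("hotspot_rate_multiplier must exceed 1")
        if self.baseline_rate * self.hotspot_rate_multiplier > 1.0:
            raise ConfigurationError(
                "hotspot death probability "
                f"{self.baseline_rate * self.hotspot_rate_multiplier:.4g} exceeds 1"
            )
        self.covariates = [c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
                           for c in self.covariates]

    @property
    def n_municipalities(self) -> int:
        return (self.n_provinces * self.districts_per_province
                * self.municipalities_per_district)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = [asdict(c) for c in self.covariates]
        return d


@dataclass
class SyntheticDataset:
    """Person table plus the generating truth.

    ``person_table`` columns: person_id, municipality_id, district_id,
    province_id, died, then one 0/1 column per configured covariate.
    ``truth`` records hotspot unit ids, the true per-unit death rate, and
    per-covariate effect sizes and prevalences.
    """

    person_table: pd.DataFrame
    truth: dict

    def write(self, persons_path: str | Path, truth_path: str | Path) -> None:
        self.person_table.to_csv(persons_path, index=False)
        Path(truth_path).write_text(json.dumps(self.truth, indent=1, sort_keys=True))

    @staticmethod
    def read(persons_path: str | Path, truth_path: str | Path) -> "SyntheticDataset":
        return SyntheticDataset(
            person_table=pd.read_csv(persons_path),
            truth=json.loads(Path(truth_path).read_text()),
        )


def _unit_ids(config: GeneratorConfig) -> pd.DataFrame:
    rows = [("ZA", "national", "")]
    for p in range(config.n_provinces):
        pid = f"P{p + 1:02d}"
        rows.append((pid, "province", "ZA"))
        for d in range(config.districts_per_province):
            did = f"{pid}-D{d + 1:02d}"
            rows.append((did, "district", pid))
            for m in range(config.municipalities_per_district):
                rows.append((f"{did}-M{m + 1:02d}", "municipality", did))
    return pd.DataFrame(rows, columns=["unit_id", "level", "parent_id"])


def generate_hierarchy(config: GeneratorConfig) -> pd.DataFrame:
    """Build the administrative tree as a (unit_id, level, parent_id) table.

    The tree is balanced: every province holds ``districts_per_province``
    districts and every district ``municipalities_per_district`` local
    municipalities.  Ids encode the path (``P03-D02-M01``), so parent links
    are acyclic by construction.
    """
    return _unit_ids(config)


def _plant_hotspots(config: GeneratorConfig, municipalities: Sequence[str]) -> list[str]:
    n_hot = int(round(config.hotspot_fraction * len(municipalities)))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    chosen = rng.choice(len(municipalities), size=n_hot, replace=False)
    return sorted(np.asarray(municipalities)[np.sort(chosen)].tolist())


def _path_indices(unit_id: str) -> list[int]:
    """P03-D02-M01 -> [3, 2, 1]; stable under hierarchy growth."""
    return [int(part[1:]) for part in unit_id.split("-")]


def _district_stream(config: GeneratorConfig, unit_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, *_path_indices(unit_id)])
    )


def _municipality_stream(config: GeneratorConfig, unit_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 1, *_path_indices(unit_id)])
    )


def generate_persons(config: GeneratorConfig, hierarchy: pd.DataFrame) -> SyntheticDataset:
    """Draw the person-level microdata over a hierarchy.

    Deaths are independent Bernoulli draws at the unit's true rate
    (baseline, or baseline x multiplier in planted hotspots).  Individual
    and household covariates are drawn per person with the prevalence that
    matches the person's municipality hotspot status; municipality-level
    covariates once per municipality; district-level covariates once per
    district, with exposure probability interpolated by the district's share
    of hotspot municipalities.
    """
    munis = hierarchy.loc[hierarchy.level == "municipality", "unit_id"].tolist()
    districts = hierarchy.loc[hierarchy.level == "district", "unit_id"].tolist()
    hot_ids = set(_plant_hotspots(config, munis))

    # district-level exposures, one Bernoulli per district per covariate
    district_exposure: dict[str, dict[str, int]] = {}
    muni_parent = hierarchy.loc[hierarchy.level == "municipality"].set_index("unit_id")["parent_id"]
    hot_share = {
        d: np.mean([m in hot_ids for m in muni_parent.index[muni_parent == d]])
        for d in districts
    }
    for did in districts:
        rng = _district_stream(config, did)
        district_exposure[did] = {}
        for cov in config.covariates:
            if cov.level == "district":
                p = (cov.prevalence_elsewhere
                     + (cov.prevalence_in_hotspots - cov.prevalence_elsewhere) * hot_share[did])
                district_exposure[did][cov.name] = int(rng.random() < p)

    n = config.persons_per_municipality
    frames = []
    true_rate: dict[str, float] = {}
    for mid in munis:
        rng = _municipality_stream(config, mid)
        hot = mid in hot_ids
        rate = config.baseline_rate * (config.hotspot_rate_multiplier if hot else 1.0)
        true_rate[mid] = rate
        did = muni_parent[mid]
        cols: dict[str, np.ndarray] = {
            "person_id": np.array([f"{mid}-{k + 1:05d}" for k in range(n)]),
            "municipality_id": np.repeat(mid, n),
            "district_id": np.repeat(did, n),
            "province_id": np.repeat(did.split("-")[0], n),
            "died": (rng.random(n) < rate).astype(np.int8),
        }
        for cov in config.covariates:
            p = cov.prevalence_in_hotspots if hot else cov.prevalence_elsewhere
            if cov.level in ("individual", "household"):
                cols[cov.name] = (rng.random(n) < p).astype(np.int8)
            elif cov.level == "municipality":
                cols[cov.name] = np.repeat(np.int8(rng.random() < p), n)
            else:  # district
                cols[cov.name] = np.repeat(np.int8(district_exposure[did][cov.name]), n)
        frames.append(pd.DataFrame(cols))

    table = pd.concat(frames, ignore_index=True)
    pi = len(hot_ids) / len(munis) if munis else 0.0
    truth = {
        "hotspot_ids": sorted(hot_ids),
        "true_rate": true_rate,
        "baseline_rate": config.baseline_rate,
        "hotspot_rate_multiplier": config.hotspot_rate_multiplier,
        "covariates": [
            {
                **asdict(cov),
                "implied_marginal_rr": implied_marginal_rr(
                    cov.prevalence_in_hotspots, cov.prevalence_elsewhere, pi
                ),
            }
            for cov in config.covariates
        ],
        "seed": config.seed,
    }
    return SyntheticDataset(person_table=table, truth=truth)


def generate_unit_counts(config: GeneratorConfig) -> pd.DataFrame:
    """Fast path: unit-level death counts without person rows.

    Each municipality's death count is a single binomial draw, which has
    exactly the distribution of the sum of its per-person Bernoulli draws.
    Intended for simulation loops (hotspot-recovery operating
    characteristics) where covariates are not needed.

    Returns one row per municipality with columns unit_id, district_id,
    province_id, population, deaths, true_rate, hotspot_true.
    """
    hierarchy = _unit_ids(config)
    munis = hierarchy.loc[hierarchy.level == "municipality"]
    hot_ids = set(_plant_hotspots(config, munis["unit_id"].tolist()))
    n = config.persons_per_municipality
    rows = []
    for mid, did in zip(munis["unit_id"], munis["parent_id"]):
        rng = _municipality_stream(config, mid)
        hot = mid in hot_ids
        rate = config.baseline_rate * (config.hotspot_rate_multiplier if hot else 1.0)
        rows.append((mid, did, did.split("-")[0], n, int(rng.binomial(n, rate)), rate, hot))
    return pd.DataFrame(rows, columns=[
        "unit_id", "district_id", "province_id",
        "population", "deaths", "true_rate", "hotspot_true",
    ])


def implied_marginal_rr(p_hot: float, p_other: float, hotspot_person_fraction: float) -> float:
    """Marginal risk ratio of hotspot residence given exposure.

    For an exposure drawn with prevalence ``p_hot`` among hotspot residents
    and ``p_other`` elsewhere, Bayes' rule gives the risk ratio
    P(hotspot | exposed) / P(hotspot | unexposed) that a single-covariate
    ecological regression targets.  Returns nan when a conditional is
    degenerate (no exposed or no unexposed stratum).
    """
    pi = hotspot_person_fraction
    num = p_hot * ((1 - p_hot) * pi + (1 - p_other) * (1 - pi))
    den = (1 - p_hot) * (p_hot * pi + p_other * (1 - pi))
    if den == 0.0:
        return float("nan")
    return num / den


def simulate_risk_model(
    log_rrs: dict[str, float],
    prevalences: dict[str, float],
    n_units: int = 248,
    persons_per_unit: int = 2500,
    baseline_prob: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Unit-level scenario in which the adjusted risk ratios are exact truth.

    Binary exposures are drawn independently per municipality with the given
    prevalences; the municipality's probability of being a hotspot is the
    log-linear ``baseline_prob * prod(RR_k ** x_k)``, so a log-link Poisson
    regression of hotspot residence on the exposures has true coefficients
    exactly ``log_rrs``.  Exposures and outcome are constant within a
    municipality (they broadcast to its ``persons_per_unit`` residents), so
    the returned table carries one row per municipality with a ``weight``
    column holding the resident count.

    Raises ConfigurationError if any exposure combination pushes the hotspot
    probability above 1.
    """
    names = list(log_rrs)
    max_prob = baseline_prob * float(np.exp(sum(max(0.0, log_rrs[k]) for k in names)))
    if max_prob > 1.0:
        raise ConfigurationError(
            f"hotspot probability reaches {max_prob:.3f} > 1 for the most exposed units"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    x = {k: (rng.random(n_units) < prevalences[k]).astype(np.int8) for k in names}
    eta = np.log(baseline_prob) + sum(log_rrs[k] * x[k] for k in names)
    hot = (rng.random(n_units) < np.exp(eta)).astype(np.int8)
    out = pd.DataFrame({
        "municipality_id": [f"U{i + 1:03d}" for i in range(n_units)],
        "hotspot": hot,
        "weight": persons_per_unit,
        **x,
    })
    return out
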