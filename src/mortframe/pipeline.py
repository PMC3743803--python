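"""End-to-end orchestration: simulate -> hotspots -> model -> attribution.

Every stage writes plain CSV/JSON artifacts into the output directory and
a ``manifest.json`` recording the configuration, seed and SHA-256 of every
output, so a rerun with an identical configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attribution, ecology, hotspots, synthetic
from .errors import ConfigurationError, ParameterError

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("mortframe")


@dataclass
class PipelineConfig:
    """Stage parameters plus either a generator block or a persons CSV path."""

    generator: synthetic.GeneratorConfig | None = None
    persons_csv: str | None = None
    alpha: float = 0.05
    screen_threshold: float = 0.10
    sandwich: str = "cr0"
    removal_rule: str = "multiplicative"
    removal_depth: int = 3
    denominator: str = "respondents"
    seed: int = 0
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.persons_csv is None):
            raise ConfigurationError("provide exactly one of generator / persons_csv")
        for name in ("alpha", "screen_threshold"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigurationError(f"{name} {value} outside (0, 1)")
        if self.removal_depth not in (1, 2, 3):
            raise ConfigurationError("removal_depth must be 1, 2 or 3")
        if self.removal_rule not in ("multiplicative", "additive"):
            raise ConfigurationError(f"unknown removal_rule {self.removal_rule!r}")
        if self.sandwich not in ("cr0", "cr1"):
            raise ConfigurationError(f"unknown sandwich flavour {self.sandwich!r}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "generator"}
        d["generator"] = self.generator.to_dict() if self.generator else None
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen = raw.pop("generator", None)
    if gen is not None:
        covs = gen.pop("covariates", None)
        if covs is not None:
            gen["covariates"] = [synthetic.CovariateSpec(**c) for c in covs]
        if "seed" not in gen and "seed" in raw:
            gen["seed"] = raw["seed"]
        gen = synthetic.GeneratorConfig(**gen)
    return PipelineConfig(generator=gen, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages and return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, index=False)
        outputs.append(path)
        return path

    # --- stage 1: obtain persons -----------------------------------------
    if config.generator is not None:
        log.info("simulating persons (%d municipalities)", config.generator.n_municipalities)
        hierarchy = synthetic.generate_hierarchy(config.generator)
        dataset = synthetic.generate_persons(config.generator, hierarchy)
        persons = dataset.person_table
        emit(persons, "persons.csv")
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
        outputs.append(truth_path)
        covariate_names = [c.name for c in config.generator.covariates]
    else:
        persons = pd.read_csv(config.persons_csv)
        required = set(synthetic.PERSON_COLUMNS)
        missing = required - set(persons.columns)
        if missing:
            raise ParameterError(
                f"stage aggregate: persons CSV missing columns {sorted(missing)}"
            )
        covariate_names = config.covariates or [
            c for c in persons.columns if c not in required
        ]

    # --- stage 2: aggregate and classify hotspots -------------------------
    units = hotspots.aggregate_persons(persons, denominator=config.denominator)
    emit(units, "units.csv")
    munis = units[units["level"] == "municipality"]
    nat = hotspots.national_proportion(munis)
    summary = hotspots.classify_hotspots(units, nat, alpha=config.alpha)
    emit(summary, "hotspot_summary.csv")
    muni_summary = summary[summary["level"] == "municipality"]
    hot_ids = set(muni_summary.loc[muni_summary["hotspot"], "unit_id"])
    log.info("national proportion %.1f per 10,000; %d hotspot municipalities",
             hotspots.PER_10K * nat, len(hot_ids))

    # --- stage 3: ecological model ----------------------------------------
    rrs: dict[str, float] = {}
    if hot_ids and covariate_names and len(hot_ids) < len(muni_summary):
        frame = ecology.ModelFrame.from_person_table(persons, summary, covariate_names)
        fit = ecology.ecological_analysis(
            frame, screen_threshold=config.screen_threshold, flavour=config.sandwich
        )
        emit(fit.table, "model_report.csv")
        diag_path = outdir / "model_diagnostics.json"
        diag_path.write_text(json.dumps(fit.diagnostics(), indent=1, sort_keys=True))
        outputs.append(diag_path)
        screened = fit.table[fit.table["screened_in"] & fit.table["adj_rr"].notna()]
        rrs = dict(zip(screened["term"], screened["adj_rr"]))
    else:
        log.warning("skipping ecological model: no hotspot/non-hotspot contrast")
        emit(pd.DataFrame(columns=["term", "unadj_rr", "unadj_ci_low", "unadj_ci_high",
                                   "unadj_p", "screened_in", "adj_rr", "adj_ci_low",
                                   "adj_ci_high", "adj_p"]), "model_report.csv")

    # --- stage 4: attribution and removal projection ----------------------
    if rrs and hot_ids:
        prevalences = (persons[persons["municipality_id"].isin(hot_ids)]
                       .groupby("municipality_id")[list(rrs)].mean()
                       .reset_index().rename(columns={"municipality_id": "unit_id"}))
        ranked = attribution.rank_factors(prevalences, rrs)
    else:
        ranked = pd.DataFrame(columns=["unit_id", "factor", "rr", "p_e", "paf", "rank"])
    emit(ranked, "attribution.csv")
    projection = attribution.project_removal(
        muni_summary, ranked, k=config.removal_depth, rule=config.removal_rule
    )
    emit(projection, "projection.csv")
    per_unit, tally = attribution.policy_table(ranked)
    emit(per_unit, "policy_table.csv")
    emit(tally, "policy_tally.csv")

    national = projection[projection["unit_id"] == "national"].iloc[0]
    summary_json = {
        "national_proportion_per_10k": float(hotspots.PER_10K * nat),
        "n_municipalities": int(len(muni_summary)),
        "n_hotspots": int(len(hot_ids)),
        "n_tests": int(len(muni_summary)),
        "projected_per_10k": {
            f"k{d}": float(national[f"projected_k{d}"])
            for d in range(1, config.removal_depth + 1)
        },
        "primary_factor_tally": tally.to_dict(orient="records"),
    }
    nat_path = outdir / "national_summary.json"
    nat_path.write_text(json.dumps(summary_json, indent=1, sort_keys=True))
    outputs.append(nat_path)

    fig_path = outdir / "removal_curves.png"
    attribution.plot_removal_curves(projection, fig_path)
    outputs.append(fig_path)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
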