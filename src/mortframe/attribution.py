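"""Population attributable fractions, factor ranking and removal projections.

For a factor with adjusted risk ratio RR and local exposure prevalence p_e
in an areal unit, the population attributable fraction is

    PAF = p_e (RR - 1) / (1 + p_e (RR - 1)),

the share of the outcome that would theoretically not occur if the exposure
were removed from that unit.  Within each hotspot municipality, factors
with RR > 1 are ranked by their local PAF (primary / secondary / tertiary);
counterfactual mortality after removing the top-k ranked factors scales the
observed rate by the ranked PAFs — multiplicatively by default,
rate * prod_{i<=k} (1 - PAF_i), or additively on the observed baseline,
rate * max(0, 1 - sum PAF_i).  Protective factors (RR < 1) yield negative
PAFs; they are reported but never ranked or removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "paf",
    "paf_ci",
    "rank_factors",
    "project_removal",
    "policy_table",
    "plot_removal_curves",
]


def paf(rr: float, p_e: float) -> float:
    """Population attributable fraction from a risk ratio and prevalence.

    Negative values (rr < 1, a protective factor) are returned as-is; the
    ranking stage treats them as non-attributable.
    """
    rr = np.asarray(rr, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    if np.any(rr <= 0):
        raise ParameterError("risk ratio must be positive")
    if np.any((p_e < 0) | (p_e > 1)):
        raise ParameterError("exposure prevalence outside [0, 1]")
    excess = p_e * (rr - 1.0)
    out = excess / (1.0 + excess)
    return float(out) if out.ndim == 0 else out


def paf_ci(rr_ci: tuple[float, float], p_e: float) -> tuple[float, float]:
    """Substitution interval: the PAF formula applied to the RR CI endpoints.

    PAF is monotone increasing in RR at fixed prevalence, so the bounds stay
    ordered.
    """
    low, high = rr_ci
    if not 0 < low <= high:
        raise ParameterError("risk-ratio CI must satisfy 0 < low <= high")
    return paf(low, p_e), paf(high, p_e)


def invert_paf(value: float, rr: float) -> float:
    """Prevalence that yields a given PAF at a given risk ratio (rr != 1)."""
    if rr == 1.0:
        raise ParameterError("prevalence is unidentified at rr = 1")
    return value / ((1.0 - value) * (rr - 1.0))


def rank_factors(
    unit_prevalences: pd.DataFrame,
    rrs: dict[str, float],
    max_rank: int = 3,
) -> pd.DataFrame:
    """Per-unit PAFs with primary/secondary/tertiary ranks.

    ``unit_prevalences`` has one row per (hotspot) unit: a ``unit_id``
    column plus one prevalence column per factor.  ``rrs`` maps factor name
    to its adjusted risk ratio.  Within each unit, factors with rr > 1 are
    sorted by descending PAF computed from that unit's own prevalence; ties
    break by larger rr, then by factor name.  Factors with rr <= 1 appear
    with rank NaN (non-attributable).

    Returns columns unit_id, factor, rr, p_e, paf, rank.
    """
    factors = [f for f in rrs if f in unit_prevalences.columns]
    missing = set(rrs) - set(factors)
    if missing:
        raise ParameterError(f"no prevalence column for factors {sorted(missing)}")
    records = []
    for _, row in unit_prevalences.iterrows():
        unit = row["unit_id"]
        entries = []
        for f in factors:
            p_e = float(row[f])
            value = paf(rrs[f], p_e)
            entries.append({"unit_id": unit, "factor": f, "rr": rrs[f],
                            "p_e": p_e, "paf": value})
        rankable = sorted(
            (e for e in entries if e["rr"] > 1.0),
            key=lambda e: (-e["paf"], -e["rr"], e["factor"]),
        )
        ranks = {e["factor"]: i + 1 for i, e in enumerate(rankable[:max_rank])}
        for e in entries:
            e["rank"] = ranks.get(e["factor"], np.nan)
        records.extend(entries)
    cols = ["unit_id", "factor", "rr", "p_e", "paf", "rank"]
    return pd.DataFrame(records, columns=cols)


def project_removal(
    unit_summary: pd.DataFrame,
    ranked: pd.DataFrame,
    k: int = 3,
    rule: str = "multiplicative",
) -> pd.DataFrame:
    """Counterfactual mortality after removing the top-k ranked factors.

    ``unit_summary`` needs unit_id, proportion (per 10,000) and population;
    ``ranked`` is the output of :func:`rank_factors`.  Units without ranked
    factors keep their observed rate.  The result has one row per unit
    (observed, projected_k1..projected_k{k}) plus a final ``national`` row
    holding population-weighted means.
    """
    if k not in (1, 2, 3):
        raise ParameterError(f"removal depth k must be 1, 2 or 3, got {k}")
    if rule not in ("multiplicative", "additive"):
        raise ParameterError(f"unknown combination rule {rule!r}")
    pafs = (ranked.dropna(subset=["rank"])
            .pivot_table(index="unit_id", columns="rank", values="paf", aggfunc="first"))
    rows = []
    for _, u in unit_summary.iterrows():
        rec = {"unit_id": u["unit_id"], "population": u["population"],
               "observed": u["proportion"]}
        unit_pafs = [
            float(pafs.loc[u["unit_id"], r])
            if u["unit_id"] in pafs.index and r in pafs.columns
            and pd.notna(pafs.loc[u["unit_id"], r]) else 0.0
            for r in (1.0, 2.0, 3.0)
        ]
        for depth in range(1, k + 1):
            if rule == "multiplicative":
                scale = float(np.prod([1.0 - p for p in unit_pafs[:depth]]))
            else:
                scale = max(0.0, 1.0 - float(np.sum(unit_pafs[:depth])))
            rec[f"projected_k{depth}"] = u["proportion"] * scale
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("observed", ascending=False, ignore_index=True)
    weights = out["population"] / out["population"].sum()
    national = {"unit_id": "national", "population": out["population"].sum(),
                "observed": float((out["observed"] * weights).sum())}
    for depth in range(1, k + 1):
        national[f"projected_k{depth}"] = float((out[f"projected_k{depth}"] * weights).sum())
    return pd.concat([out, pd.DataFrame([national])], ignore_index=True)


def policy_table(ranked: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary attributable factor per hotspot unit, plus the national tally.

    Returns (per_unit, tally): per_unit has one row per unit with a rank-1
    factor (unit_id, primary_factor, paf); tally counts how many units each
    factor leads and its share of all led units.
    """
    primary = (ranked[ranked["rank"] == 1]
               .loc[:, ["unit_id", "factor", "paf"]]
               .rename(columns={"factor": "primary_factor"})
               .sort_values("unit_id", ignore_index=True))
    if primary.empty:
        tally = pd.DataFrame(columns=["factor", "n_units", "share"])
        return primary, tally
    counts = primary["primary_factor"].value_counts()
    tally = pd.DataFrame({
        "factor": counts.index,
        "n_units": counts.to_numpy(),
        "share": counts.to_numpy() / len(primary),
    }).sort_values(["n_units", "factor"], ascending=[False, True], ignore_index=True)
    return primary, tally


def plot_removal_curves(projection: pd.DataFrame, path) -> None:
    """Observed and projected mortality over units ordered high to low.

    One curve per removal depth, with horizontal dashed lines at the
    national population-weighted aggregates, mirroring the standard
    removal-projection figure layout.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = projection[projection["unit_id"] != "national"]
    national = projection[projection["unit_id"] == "national"].iloc[0]
    depths = [c for c in projection.columns if c.startswith("projected_k")]
    x = np.arange(len(units))
    fig, ax = plt.subplots(figsize=(9, 5))
    shades = {"observed": "black", "projected_k1": "0.35",
              "projected_k2": "0.55", "projected_k3": "0.75"}
    for col in ["observed", *depths]:
        ax.plot(x, units[col], color=shades.get(col, "0.6"),
                label=col.replace("projected_k", "after removing top "))
        ax.axhline(national[col], color=shades.get(col, "0.6"),
                   linestyle="--", linewidth=0.8)
    ax.set_xlabel("local municipalities, ordered by descending observed mortality")
    ax.set_ylabel("deaths per 10,000")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
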