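"""Ecological regression of hotspot residence on multilevel determinants.

The outcome is person-level residence in a hotspot municipality (a unit
attribute broadcast to residents).  Because the outcome is prevalent,
risk ratios are estimated directly with a modified Poisson approach: a
log-link Poisson GLM fitted to the binary outcome, whose standard errors
are then corrected with a cluster-robust (sandwich) variance clustered on
the municipality — ordinary Poisson standard errors on binary data are
under-dispersed, and residents of one municipality share the outcome.

Candidate determinants are first screened one at a time (bivariate stage);
those significant at the 10% level enter the multivariable model.  Both
stages run on data collapsed to unique (municipality, covariate-pattern)
cells with frequency weights, which leaves estimates and the cluster
sandwich unchanged while keeping fits fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .errors import ModelError, ParameterError

__all__ = [
    "ModelFrame",
    "EcologicalFit",
    "cluster_robust_vcov",
    "bivariate_screen",
    "fit_multivariable",
    "ecological_analysis",
    "describe_by_hotspot",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ModelFrame:
    """Person (or collapsed cell) data ready for the hotspot regression.

    ``data`` must hold the binary outcome column, the cluster id column and
    the covariate columns; an optional ``weight`` column carries cell counts
    when rows are pre-aggregated.
    """

    data: pd.DataFrame
    covariates: list[str]
    outcome: str = "hotspot"
    cluster: str = "municipality_id"
    weight: str | None = None

    def __post_init__(self) -> None:
        for col in [self.outcome, self.cluster, *self.covariates]:
            if col not in self.data.columns:
                raise ParameterError(f"column {col!r} missing from model frame")
        if self.data[self.cluster].isna().any():
            raise ParameterError("cluster id must be non-missing")
        # outcome is a unit attribute: constant within each cluster
        per_cluster = self.data.groupby(self.cluster)[self.outcome].nunique()
        if (per_cluster > 1).any():
            bad = per_cluster[per_cluster > 1].index[0]
            raise ParameterError(f"outcome varies within cluster {bad!r}")

    @classmethod
    def from_person_table(
        cls,
        persons: pd.DataFrame,
        hotspot_summary: pd.DataFrame,
        covariates: list[str],
    ) -> "ModelFrame":
        """Join the municipality hotspot flag onto person records."""
        flags = hotspot_summary.loc[
            hotspot_summary["level"] == "municipality", ["unit_id", "hotspot"]
        ].rename(columns={"unit_id": "municipality_id"})
        data = persons.merge(flags, on="municipality_id", how="inner", validate="m:1")
        data["hotspot"] = data["hotspot"].astype(np.int8)
        return cls(data=data, covariates=covariates)

    def collapsed(self, covariates: list[str] | None = None) -> "ModelFrame":
        """Aggregate to unique (cluster, covariate pattern) cells."""
        covs = self.covariates if covariates is None else covariates
        keys = [self.cluster, self.outcome, *covs]
        if self.weight is None:
            cells = self.data.groupby(keys, sort=True).size().rename("weight").reset_index()
        else:
            cells = (self.data.groupby(keys, sort=True)[self.weight]
                     .sum().rename("weight").reset_index())
        return ModelFrame(cells, covariates=covs, outcome=self.outcome,
                          cluster=self.cluster, weight="weight")

    @property
    def n_clusters(self) -> int:
        return self.data[self.cluster].nunique()

    @property
    def n_obs(self) -> int:
        if self.weight is None:
            return len(self.data)
        return int(self.data[self.weight].sum())


@dataclass
class EcologicalFit:
    """Two-stage model report in the layout of a determinants table."""

    table: pd.DataFrame  # term, unadj_rr/ci/p, screened_in, adj_rr/ci/p
    n_clusters: int
    n_obs: int
    screen_threshold: float
    dropped_terms: list[str] = field(default_factory=list)
    excluded_terms: dict[str, str] = field(default_factory=dict)
    converged: bool = True

    def diagnostics(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "screen_threshold": self.screen_threshold,
            "dropped_terms": self.dropped_terms,
            "excluded_terms": self.excluded_terms,
            "converged": self.converged,
        }


def cluster_robust_vcov(result, groups, correction: str = "cr0") -> np.ndarray:
    """CR sandwich covariance for a fitted log-link Poisson GLM.

    bread = inverse expected information X' diag(w mu) X; meat = sum over
    clusters of outer products of summed score contributions
    w_i x_i (y_i - mu_i).  ``correction="cr0"`` applies no small-sample
    factor; ``"cr1"`` scales by G/(G-1).  With every observation its own
    cluster, CR0 reduces to the HC0 heteroskedasticity-robust covariance.
    """
    if correction not in ("cr0", "cr1"):
        raise ParameterError(f"unknown sandwich correction {correction!r}")
    groups = np.asarray(pd.factorize(np.asarray(groups))[0])
    n_groups = int(groups.max()) + 1 if groups.size else 0
    if n_groups < 2:
        raise ModelError("cluster-robust variance needs at least 2 clusters")
    X = np.asarray(result.model.exog, dtype=float)
    y = np.asarray(result.model.endog, dtype=float)
    mu = np.asarray(result.mu, dtype=float)
    w = np.asarray(getattr(result.model, "freq_weights", np.ones_like(y)), dtype=float)

    bread = np.linalg.inv(X.T @ (X * (w * mu)[:, None]))
    scores = X * (w * (y - mu))[:, None]
    cluster_scores = np.zeros((n_groups, X.shape[1]))
    np.add.at(cluster_scores, groups, scores)
    meat = cluster_scores.T @ cluster_scores
    vcov = bread @ meat @ bread
    if correction == "cr1":
        vcov = vcov * n_groups / (n_groups - 1)
    return vcov


def _fit_poisson(frame: ModelFrame, covariates: list[str], flavour: str = "cr0"):
    """Fit the log-link Poisson GLM on collapsed cells; return (result, vcov, X columns)."""
    cells = frame.collapsed(covariates)
    y = cells.data[frame.outcome].to_numpy(dtype=float)
    w = cells.data["weight"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y))] +
                        [cells.data[c].to_numpy(dtype=float) for c in covariates])
    names = ["intercept", *covariates]

    # drop aliased columns by pivoted QR on the weighted design
    kept = list(range(X.shape[1]))
    if X.shape[1] > 1:
        _, r, piv = qr(X * np.sqrt(w)[:, None], mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        kept = sorted(piv[:rank].tolist())
        if 0 not in kept:  # never drop the intercept
            kept = [0] + kept[: len(kept) - 1]
    dropped = [names[i] for i in range(X.shape[1]) if i not in kept]
    X = X[:, kept]
    names = [names[i] for i in kept]

    model = sm.GLM(y, X, family=sm.families.Poisson(), freq_weights=w)
    result = model.fit(maxiter=200)
    if not result.converged:
        raise ModelError(
            f"Poisson IRLS did not converge: deviance trace {result.fit_history['deviance']}"
        )
    vcov = cluster_robust_vcov(result, cells.data[frame.cluster], correction=flavour)
    return result, vcov, names, dropped, cells


def _term_row(beta: float, se: float) -> dict:
    return {
        "rr": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - _Z975 * se)),
        "ci_high": float(np.exp(beta + _Z975 * se)),
        "p": float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0,
    }


def bivariate_screen(
    frame: ModelFrame,
    covariate: str,
    threshold: float = 0.10,
    flavour: str = "cr0",
) -> dict:
    """One-covariate modified Poisson fit with cluster-robust p-value.

    Returns a dict with rr, ci_low, ci_high, p, screened_in and a note.
    Degenerate inputs (constant exposure; an exposure stratum in which the
    outcome never or always occurs, where the log-link MLE sits at the
    boundary) are reported with ``degenerate=True`` and are never screened
    in.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"screen threshold {threshold} outside (0, 1)")
    data = frame.data
    weights = (data[frame.weight] if frame.weight else pd.Series(1.0, index=data.index))
    x = data[covariate]
    wsum = weights.groupby(x).sum()
    if x.nunique() < 2:
        return {"term": covariate, "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "screened_in": False, "degenerate": True,
                "note": "zero exposure variance"}
    m = (data[frame.outcome] * weights).groupby(x).sum() / wsum
    if (m == 0.0).any():
        # log-link MLE at the boundary: outcome never occurs in a stratum
        exposed, unexposed = m.loc[m.index.max()], m.loc[m.index.min()]
        rr = np.inf if exposed > unexposed else 0.0
        return {"term": covariate, "rr": float(rr), "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "screened_in": False, "degenerate": True,
                "note": "boundary fit: outcome absent in an exposure stratum"}
    result, vcov, names, _, _ = _fit_poisson(frame, [covariate], flavour)
    i = names.index(covariate)
    row = _term_row(result.params[i], float(np.sqrt(vcov[i, i])))
    row.update(term=covariate, screened_in=bool(row["p"] < threshold),
               degenerate=False, note="")
    return row


def fit_multivariable(
    frame: ModelFrame,
    covariates: list[str],
    flavour: str = "cr0",
) -> pd.DataFrame:
    """Adjusted risk ratios with cluster-robust 95% CIs.

    Returns one row per retained term (intercept included): rr, ci_low,
    ci_high, p.  Aliased design columns are dropped and reported via the
    ``dropped`` DataFrame attr.  With no covariates the intercept fit
    returns exp(alpha) = the overall outcome prevalence.
    """
    if frame.n_clusters < 2:
        raise ModelError("need at least 2 municipalities to fit the ecological model")
    result, vcov, names, dropped, _ = _fit_poisson(frame, covariates, flavour)
    rows = []
    for i, name in enumerate(names):
        row = _term_row(result.params[i], float(np.sqrt(vcov[i, i])))
        row["term"] = name
        rows.append(row)
    table = pd.DataFrame(rows)[["term", "rr", "ci_low", "ci_high", "p"]]
    table.attrs["dropped"] = dropped
    table.attrs["converged"] = bool(result.converged)
    return table


def ecological_analysis(
    frame: ModelFrame,
    candidates: list[str] | None = None,
    screen_threshold: float = 0.10,
    flavour: str = "cr0",
) -> EcologicalFit:
    """Run the screen-then-adjust pipeline and assemble the report table."""
    candidates = frame.covariates if candidates is None else candidates
    screen_rows, screened, excluded = [], [], {}
    for cov in candidates:
        row = bivariate_screen(frame, cov, threshold=screen_threshold, flavour=flavour)
        screen_rows.append(row)
        if row["degenerate"]:
            excluded[cov] = row["note"]
        elif row["screened_in"]:
            screened.append(cov)
    adj = fit_multivariable(frame, screened, flavour=flavour) if screened else None

    records = []
    for row in screen_rows:
        rec = {
            "term": row["term"],
            "unadj_rr": row["rr"], "unadj_ci_low": row["ci_low"],
            "unadj_ci_high": row["ci_high"], "unadj_p": row["p"],
            "screened_in": row["screened_in"],
            "adj_rr": np.nan, "adj_ci_low": np.nan, "adj_ci_high": np.nan, "adj_p": np.nan,
        }
        if adj is not None and row["term"] in set(adj["term"]):
            a = adj.set_index("term").loc[row["term"]]
            rec.update(adj_rr=a["rr"], adj_ci_low=a["ci_low"],
                       adj_ci_high=a["ci_high"], adj_p=a["p"])
        records.append(rec)
    return EcologicalFit(
        table=pd.DataFrame(records),
        n_clusters=frame.n_clusters,
        n_obs=frame.n_obs,
        screen_threshold=screen_threshold,
        dropped_terms=list(adj.attrs["dropped"]) if adj is not None else [],
        excluded_terms=excluded,
        converged=bool(adj.attrs["converged"]) if adj is not None else True,
    )


def describe_by_hotspot(
    persons: pd.DataFrame,
    hotspot_ids: set[str],
    columns: list[str],
) -> pd.DataFrame:
    """Descriptive comparison of covariate means by hotspot residence.

    A Table-2-style report: per covariate, the mean (prevalence for 0/1
    exposures) with a normal-approximation 95% CI in hotspot and remaining
    municipalities.  Purely descriptive; the modelling path uses the
    cluster-robust Poisson screen instead.
    """
    in_hot = persons["municipality_id"].isin(hotspot_ids)
    rows = []
    for col in columns:
        rec = {"factor": col}
        for label, mask in (("hotspot", in_hot), ("other", ~in_hot)):
            v = persons.loc[mask, col].astype(float)
            mean = v.mean()
            se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            rec[f"{label}_n"] = int(len(v))
            rec[f"{label}_mean"] = mean
            rec[f"{label}_ci_low"] = mean - _Z975 * se
            rec[f"{label}_ci_high"] = mean + _Z975 * se
        rows.append(rec)
    return pd.DataFrame(rows)
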