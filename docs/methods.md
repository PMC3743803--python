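# Methods

`mortframe` implements a small-area mortality analysis pipeline for
household-survey-style microdata over a four-level administrative hierarchy
(national → province → district → local municipality). This note records
the statistical model at each stage, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the design
choices made where more than one defensible option existed.

## Hotspot detection

For an areal unit with `d` deaths among `n` adults aged 15–59, the mortality
proportion is `10,000 · d/n`. The exact two-sided 95% confidence interval is
the Clopper–Pearson interval, computed from beta quantiles
`Beta(α/2; d, n−d+1)` and `Beta(1−α/2; d+1, n−d)`, with the conventional
limits 0 at `d = 0` and 1 at `d = n`. Clopper–Pearson was chosen as the
canonical "exact binomial" interval; it is conservative by construction, so
empirical coverage is at or above the nominal level.

A unit is a **hotspot** when the lower limit of that interval (a one-sided
tail probability of 0.025) strictly exceeds the national average proportion.
Boundary equality is classified as *not* a hotspot. The national average is
the pooled deaths over pooled population of the same dataset, treated as a
fixed reference constant without its own sampling uncertainty, and a unit's
own deaths are not excluded from it. The standardised mortality ratio is
`d / (n · p_national)`.

No multiple-testing correction is applied by default — the number of tests
is reported, and Bonferroni or Benjamini–Hochberg switches are available via
`classify_hotspots(..., correction=...)`, implemented through the duality
between the interval rule and the one-sided exact binomial p-value
`P(X ≥ d | p_national)`.

The aggregation step exposes a `denominator` choice: `respondents` (all
enumerated persons, the default) or `midyear` (respondents minus half the
deaths). Survey denominators are usually respondent counts, so that is the
default; the option exists because denominator conventions differ between
survey and vital-registration traditions.

## Ecological model of hotspot membership

The outcome `Y_ij` is whether person `i` resides in hotspot municipality
`j` — a unit attribute broadcast to residents, hence constant within a
cluster. Because the outcome is prevalent, odds ratios would overstate risk;
risk ratios are estimated directly by **modified Poisson regression**: a
log-link Poisson GLM fitted to the binary outcome,

    log E[Y_ij] = α + Σ_k β_k x_kij,    RR_k = exp(β_k),

with standard errors from a **cluster-robust sandwich** clustered on the
municipality. Fitting a Poisson likelihood to Bernoulli data misstates the
variance, and residents of one municipality share `Y`; the sandwich repairs
both.

The sandwich is implemented directly (`cluster_robust_vcov`): bread is the
inverse expected information `X′ diag(w μ) X`; meat is the sum over clusters
of outer products of within-cluster summed score contributions
`w_i x_i (y_i − μ_i)`. The default flavour is CR0 (no small-sample factor);
CR1-style `G/(G−1)` scaling is available by flag. With every observation its
own cluster, CR0 reduces exactly to HC0 — a property the test suite checks
numerically, alongside agreement with an independent library implementation
of the cluster estimator. Confidence intervals are Wald `exp(β ± 1.96·SE)`
on the log scale.

Candidate determinants are screened one at a time; those with cluster-robust
`p < 0.10` enter the multivariable model (the threshold is configurable).
Degenerate screens — zero exposure variance, or an exposure stratum in which
the outcome never occurs (the log-link MLE sits at the boundary) — are
reported as such, never screened in, and never crash. Aliased design
columns are removed by pivoted-QR rank detection and reported. A closed-form
identity anchors correctness: on any collapsed 2×2 table, the log-link
Poisson MLE is exactly the prevalence ratio between exposure strata.

Both stages run on data collapsed to unique (municipality, covariate
pattern) cells with frequency weights. For a log-link Poisson model this is
an exact reformulation — the likelihood, score and clustered sandwich are
identical — and it makes simulation studies with hundreds of replicates at
survey scale cheap.

A descriptive comparison of covariate distributions between hotspot and
remaining municipalities (`describe_by_hotspot`) is provided for reporting;
the Poisson screen is the modelling path.

## Population attributable fractions and removal projections

For a factor with adjusted risk ratio RR and exposure prevalence `p_e` in a
given unit,

    PAF = p_e (RR − 1) / (1 + p_e (RR − 1)).

PAF is strictly increasing in both arguments (for `RR > 1`, `p_e > 0`) and
tends to `(RR−1)/RR` as `p_e → 1`. Negative PAFs (protective factors) are
reported but never ranked or removed. Interval estimates use **RR-CI
substitution**: the formula applied to the RR confidence limits at fixed
`p_e`; since PAF is monotone in RR the bounds stay ordered. Substitution
reproduces the published worked-example intervals; delta-method or bootstrap
intervals would propagate prevalence uncertainty too, but prevalence in this
design is a near-census unit quantity, so substitution is the default.

Within each hotspot unit, factors with `RR > 1` are ranked by descending
PAF computed from the unit's own (person-weighted) exposure prevalence;
ties break by larger RR, then by factor name. Ranks 1–3 are primary,
secondary, tertiary.

Counterfactual removal of the top-`k` factors scales the observed rate.
Two combination rules are implemented because the correct one is genuinely
ambiguous when PAFs of co-occurring exposures are combined:

- **multiplicative** (default): `rate × Π_{i≤k} (1 − PAF_i)` — never
  negative, monotone in `k`, treats removals as sequential;
- **additive** on the observed baseline: `rate × max(0, 1 − Σ_{i≤k} PAF_i)`
  — matches back-of-envelope burden subtraction, floored at zero.

At `k = 1` the two rules coincide. National aggregates are
population-weighted means across units; the projection artefact orders units
by descending observed mortality and the plotting helper renders observed
plus `k = 1..3` curves with dashed national aggregate lines.

## Cause-specific fractions

A region's cause-specific fraction is `100 · cause count / total deaths`,
carried at full precision internally and rounded to 2 d.p. only at report
time. Top-five tables are partial partitions, so per-region CSFs need not
sum to 100% (a full partition does, within rounding — tested). Cause labels
are opaque strings; no ICD-10 parsing or ill-defined-cause redistribution is
attempted. Cross-region association between CSFs and all-cause mortality
uses the Pearson product-moment coefficient with its two-sided t-based
p-value; zero-variance input is an error. The package bundles the South
Africa 2007 provincial top-five vital-registration tabulation as a small CSV
worked-example dataset.

## Synthetic-data generator

The generator emulates the *structure* of a national cross-sectional
mortality survey, not any particular population:

- a balanced hierarchy, default 9 provinces × 6 districts × 5
  municipalities (270 units, matching the ~250-municipality scale of the
  motivating setting);
- 2,500 adults per municipality (≈640,000 persons nationally, the scale of
  the motivating survey);
- deaths as independent Bernoulli draws per person at the unit's true rate —
  baseline 0.0145 (145 per 10,000), times 2.2 in planted hotspots. The
  multiplier reflects that observed high-risk districts run at twice the
  national rate or more; 27% of municipalities are planted (a 67-in-248-style
  share);
- binary exposures drawn with hotspot-dependent prevalences. The defaults
  reconcile the worked example's overall prevalences (0.52, 0.62, 0.39,
  0.01, 0.42) with its hotspot/non-hotspot contrasts under a 27% hotspot
  population share.

Randomness derives from one seed through `SeedSequence` substreams keyed by
the unit's hierarchy path, so enlarging the hierarchy never changes draws
for existing units, and a fixed seed gives byte-identical output.
`generate_unit_counts` is a fast path that draws each municipality's death
count as a single binomial — exactly the distribution of the summed
Bernoulli draws — for simulation loops that need no covariates.

**What the generator does not emulate:** household clustering of deaths,
age/sex structure, survey weights and non-response, spatially autocorrelated
risk surfaces, and between-unit heterogeneity in covariate prevalence beyond
the two-level hotspot/non-hotspot contrast. The last point matters for
interpreting simulated confidence intervals: real ecological data carry
extra between-cluster prevalence variation, so robust intervals on real data
are wider than on data from this generator. Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
generating process, not performance on any real survey.

Conditional-prevalence generation (exposures drawn given hotspot status)
mirrors how determinants tables are built, but under it the *joint* adjusted
log-link RRs have no closed form. Parameter-recovery and coverage
simulations therefore use `simulate_risk_model`, which reverses the
direction: unit-level exposures are drawn independently and hotspot status
is Bernoulli with probability `exp(α + Σ β_k x_k)`, making `exp(β_k)` the
exact estimand of the fitted model. The recorded truth object of the main
generator includes, per covariate, the Bayes-implied *marginal* risk ratio
under person-level mixing, which is exact for individual-level exposures and
approximate for district-level ones.

## Numerical and degenerate-input choices

- Interval limits at `d = 0` and `d = n` are set to 0 and 1 exactly, not by
  quantile evaluation.
- Hotspot rule uses strict inequality; SMR requires positive expected
  deaths; proportions require positive population — violations raise typed
  errors rather than returning NaN.
- IRLS is capped at 200 iterations; non-convergence raises an error carrying
  the deviance trace.
- Ranking tie-breaks and cause-ranking tie-breaks are deterministic
  (documented above), so artefacts are byte-stable across reruns; the
  pipeline manifest records SHA-256 hashes of every output and identical
  configurations reproduce identical manifests.

## Problem sizes used in the test suite

Simulation-based tests use: 100 seeds of the 270-unit × 2,500-person design
for hotspot recovery; 400 replicates of a 248-unit design for RR recovery
and CI coverage (collapsed-cell fitting makes these cheap); 2,000 binomial
replicates for interval coverage; 300 replicates for the null screening
rate; 800 nine-region replicates for the correlation check. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

- The ecological design identifies associations between area-level hotspot
  membership and exposure prevalence; PAFs inherit any unmeasured
  confounding in the adjusted RRs, and removal projections are theoretical
  ceilings, not forecasts.
- Combining PAFs across correlated exposures has no uniquely correct rule;
  both implemented rules ignore exposure co-occurrence within persons.
- The generator's two-level prevalence structure understates real
  between-unit heterogeneity (see above).
- No spatial smoothing, shrinkage or scan statistics: units are exchangeable
  given their own counts, and the hotspot rule is aspatial given unit
  membership.
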