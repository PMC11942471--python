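# Methods

## Data model and harmonization

The pipeline consumes long-format CSV count tables (`department, year,
category, count`) from four registry-like sources.  Department labels are
canonicalized (uppercase, diacritics stripped, whitespace collapsed, optional
alias map) because administrative tables habitually mix accented and
unaccented spellings.  Tables are pivoted onto the configured
department × year grid; a cell absent from the input is **missing**, not
zero — violence registries contain genuine all-zero series, and conflating
the two would corrupt both the shares and the σ = 0 handling downstream.
Every cell carries a provenance flag (`observed | missing | imputed`).

Missing cells are filled per (department, column) series by linear
interpolation against the year values; leading/trailing gaps take the
nearest observed value, since linear interpolation is undefined beyond the
observed range.  Imputation is idempotent and never touches observed cells;
a series with no observations at all is an error rather than a silent zero.

## Indicators

Ten indicators per department-year, in four families (shares ×100, violence
shares ×1000, death rates ×1000, fertility rates ×1000); all use affiliated
women as the population denominator — the index deliberately measures risk
within the insured population rather than against census projections.  Any
zero denominator yields a missing value, never 0.  Subgroup counts exceeding
their totals are data-consistency errors for the share-type indicators; the
fertility rates carry no such bound because births are not a subset of
affiliations.

The violence-share scale deserves a note: the formula convention for DVAW
and DVAC is sometimes printed as a percentage (×100), but published
departmental values of these indicators (medians in the hundreds, maxima at
1000) are only consistent with a per-1000 share.  The default is therefore
×1000 and the scale is configurable (`dv_scale`).

"IFR" follows the field's (misleading) label: births to mothers ≤14 per
1000 affiliated girls 10–14 — child-mother fertility, not infant fertility.

## Standardization and segmentation

Z-scores use the population σ (divide by N), pooled per indicator over all
department-years; pooling keeps the longitudinal dataset on a single scale
per indicator.  Within-year pooling is available as a sensitivity option
(`pool="by_year"`).  A σ = 0 indicator standardizes to all zeros with an
explicit degeneracy warning.  Sample-σ (ddof=1) is available as a flag;
z-scores differ only by a constant factor, so every rank-based downstream
result is unchanged.

The longitudinal dataset holds the standardized risk indicators for every
department-year and excludes the fertility indicators by construction (they
define the outcome).  The candidate predictor set defaults to
{PIW, PMW, PSW, DVAW, DVAC, CHR, SR}: the six structural/violence indicators
plus the suicide rate, which the refined models treat as a candidate on the
same footing; the set is configurable.  The aggregated dataset has one row
per department: standardized predictors averaged over the index window
(default 2019–2021) joined with the relative fertility changes
Δ = (v_t − v_{t−1})/v_{t−1} × 100 for the configured year pair (default
2020→2021 — pandemic-year conceptions surfacing as maternities) and their
standardized versions.  A zero baseline makes Δ missing with a logged
exclusion; if more than half the departments lack a usable pair the run
aborts with a coverage error.

## Index construction and GLM refinement

The GLM is Gaussian with identity link and intercept; for this family the
reported p-values are two-sided t tests on residual degrees of freedom
(equivalent to OLS inference), and pseudo-R² = 1 − residual/null deviance.
Other families (poisson, gamma, binomial) are configurable and use
large-sample z tests.  Constant predictor columns are dropped with a
warning; singular designs raise an error naming the collinear columns.

Backward elimination drops one predictor at a time — the largest p-value
above α (default 0.05) — and refits, stopping when all remaining droppable
p-values are ≤ α.  One-at-a-time removal is preferred to simultaneous
removal because jointly informative predictors can look individually weak;
the audit trail records every drop with its p-value and the deviance /
pseudo-R² change (residual deviance is non-decreasing along the path).  A
keep-list can pin predictors that should survive regardless of
significance.  If everything is eliminated the result is an intercept-only
fit plus a warning, and the index scores degenerate to zero.

Final weights are equal (w_i = 1/k) over the retained set, the convention
for this index family; `glm_coefficients` mode (fitted standardized
coefficients as weights) is offered for sensitivity analysis.

Two outcome conventions exist because composite-index studies use both:

* **delta_outcome** (default, recommended): prune against the standardized
  fertility-change outcome (Z_ΔEFR by default).  The predictors and the
  outcome are distinct data, so the fit is informative.
* **circular_composite**: regress the equal-weight composite of the candidate
  indicators on those same indicators, prune, re-aggregate.  The first
  stage is exactly circular — the outcome is a linear combination of the
  predictors, so pseudo-R² = 1 to machine precision and all p-values
  collapse; the mode exists to reproduce that published convention and is
  flagged loudly in the logs.  Its near-saturated numbers must not be read
  as predictive performance.

## Validation

Spearman's ρ between EFFI and each standardized Δ outcome, with average
ranks for ties, pairwise deletion of missing pairs, and two-sided p-values:
the exact permutation distribution (all n! permutations) for n < 10 and the
t approximation with n − 2 df otherwise — exactness where it is cheap,
convention where it is not; with ~33 departments the t path is operative.
Because Spearman is invariant under strictly increasing transforms, ρ on Δ
and on Z_Δ are identical; the tests use this as a cross-module check.
Interpretation follows a sign rule with |ρ| < 0.1 (configurable) read as
"no link".  No multiplicity correction is applied across the three
correlations; with three highly dependent outcomes a correction would be
cosmetic, and the correlations are reported jointly.

## Synthetic generator

The generator emits raw count tables, not indicators, so harmonization and
indicator computation are exercised rather than bypassed.  Per department a
latent fragility F_d ~ N(0,1) drives:

* affiliated-women totals: log-normal across departments (median ≈ 10⁵,
  log-sd 1.0) with 2% year-to-year noise; age bands 10–14 / 15–19 are
  binomial thinnings at 4% each;
* subgroup affiliations: binomial with logit-linear proportions,
  logit(p_base) + λ_channel·F_d + ε;
* births: Poisson with log-rate linear in F_d plus a shock·F_d term in 2021
  only;
* violence and death subgroups: binomial with F_d-linked rates; with
  probability `zero_inflation` a department's women-victim channel is zeroed
  for all years (the all-zero series real registries contain);
* missingness: each cell dropped with probability `missing_rate`, never
  emptying a series.

Default conditions (chosen once as the study conditions and not tuned):
33 departments, 2019–2022, loadings 0.5 on PIW/PSW/CHR, 0.3 on
PMW/SR/fertility, 0.2 on DVAW/DVAC, shock 0.4, cell noise sd 0.1, 2%
missingness, 5% zero-inflation.  Base rates are anchored to the magnitudes
published for Colombian departments: IFR ≈ 1.5 and AFR ≈ 30 per 1000
affiliated women, DVAW ≈ 320 and DVAC ≈ 100 per 1000 cases, SR ≈ 11 and
CHR ≈ 5 per 1000 deaths, subsidized share ≈ 60%.  The documented
high-signal regime (`high_signal_config`: loadings 0.8 on PIW/PSW/CHR, 0.5
on fertility, shock 0.5, noise 0.02, no missingness) is the recovery
benchmark: over 50 replicates the median Spearman between the recovered
index and the planted F_d exceeds the pre-registered 0.80 threshold.

What the generator does **not** emulate: spatial correlation between
departments, reporting artifacts and under-registration, age-structure
drift, migration waves, or the actual departmental distributions of any
country — department labels are synthetic (`D01`…).  Passing recovery tests
therefore show that the pipeline recovers a monotone latent signal under
its own structural assumptions, not that the index is valid on real
registries.

## Numerical choices and degenerate inputs

* σ = 0 → zeros + warning (standardizer); zero rank variance → explicit
  undefined-correlation error (Spearman); zero baseline → missing + logged
  exclusion (Δ); all-missing series → error (imputation) or "NA"
  (summaries).
* Exact permutation p-values treat |ρ_perm| ≥ |ρ_obs| with a 1e-12 slack to
  make ties in the permutation distribution deterministic.
* CSV artifacts are written with a 12-significant-digit float format so
  reruns are byte-identical; a manifest stores SHA-256 checksums per
  artifact and a hash of the scientific configuration (output paths
  excluded).
* Problem sizes in the test-suite simulations (50 recovery replicates, 1000
  null-calibration replicates at n = 33, 200 oracle vectors) were chosen as
  the smallest sizes at which the binomial/Monte-Carlo tolerances quoted in
  the tests are meaningful.

## Known limitations

* Affiliation-based denominators undercount the uninsured; the indicators
  measure risk within the insured population.
* Backward elimination under a pure-noise outcome retains each predictor
  slightly above the nominal rate (≈5–6% at α = 0.05, measured over 1000
  replicates) because the last survivor's refitted p-value is
  selection-biased; the model usually (≈70%) empties entirely.  Stepwise
  retention is a screening device, not a severity-controlled test.
* The GLM assumes linear mean structure; equal weights assume exchangeable
  indicator importance.  Alternative weighting (PCA, learned weights) is
  out of scope.
* With ~33 departments the validation correlations carry wide sampling
  bands; interpretation thresholds (|ρ| < 0.1) are conventions, not tests.
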