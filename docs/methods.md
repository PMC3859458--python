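# Methods

This note records the statistical model, the defaults and the design
choices behind `cutpointsurv`, in the spirit of a package vignette. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Preprocessing

Raw marker scores live on a bounded (0, 255] fluorescence scale and are
right-skewed, so all modeling happens on `z = (log2 m − median)/(k·MAD)`
computed **per cohort**. Consequences and choices:

- `k` (`mad_constant`) defaults to 1.4826, the constant that makes the
  MAD consistent for the standard deviation under normality and the
  default of the common statistical environments. It is exposed because
  nothing in the analysis depends on the convention as long as the same
  one is used on both cohorts.
- Per-cohort standardization is deliberate and consequential: a learned
  threshold is a *scaled distance from each trial's own median*, not an
  absolute assay level. This is the only reading under which a threshold
  is portable across cohorts whose raw score distributions differ (assay
  drift, different eligibility), and it is how `run_validation` applies a
  frozen threshold.
- The median of an even-sized sample is the mean of the two central order
  statistics. A score exactly at the threshold classifies **high**; with
  continuous scores the tie has measure zero, but the rule must exist and
  is serialized with the threshold.
- Stage-IIIB records are excluded before any inference (`filter_stage_iv`)
  because a design in which one stage appears in only one arm cannot
  support a stage-by-treatment term.

## Cut-point model

For marker value `z` and candidate cut-point `c` the hazard is

    h(t|x) = h0(t) exp( β₁ treat + βᵀ covariates + γ₁ 1{z≥c} + γ₂ treat·1{z≥c} )

maximized by Newton–Raphson on the **Efron-ties** partial likelihood.
The cut-point machinery commits to:

- **Grid**: observed unique standardized marker values inside the
  10th–90th percentile span. Cut-points between the same adjacent order
  statistics are likelihood-equivalent, so observed values lose nothing;
  the interior span keeps both groups away from degenerate sizes. When a
  cohort has more unique values than `grid_max_points` (default 50), the
  grid is thinned to evenly spaced order statistics — adjacent grid
  points differ by at most a couple of order statistics, which is far
  below the sampling noise of the estimated cut-point, and it bounds the
  scan at 50 Cox fits.
- **Posterior**: uniform prior over the grid times `exp ℓ*(c)`, the
  maximized partial likelihood at each `c` (a profile pseudo-posterior).
  This is deterministic and reproducible — no MCMC. The operational
  threshold is the weighted median (smallest grid value with cumulative
  weight ≥ ½); the central 95% interval is reported alongside.
  Under the null the posterior is diffuse but not exactly uniform: the
  profile log-likelihood fluctuates on the scale of a χ² maximum across
  the grid, so single-replicate summaries of "closeness to the prior"
  have a wide null distribution. The test suite therefore checks the
  replicate-averaged posterior CDF against the prior.
- **Evidence**: BIC-approximated log Bayes factors,
  `log BF ≈ Δℓ − ½ Δk · log(events)`, with the interaction charged two
  parameters (indicator + interaction) and histology two (dummy pair,
  adenocarcinoma reference). The entry/retention bar is log BF = 3
  ("positive evidence"); the null simulations in the acceptance suite
  verify that this controls the interaction false-positive rate below
  10% at n = 300.
- **Screen/build loop**: add the single best candidate above the bar
  (markers screened over their full cut-point grid, conditional on the
  current model), then refit jointly and drop any term whose evidence
  fell below the bar; iterate to a fixed point (cap 10 cycles, default).
  Equal evidence breaks lexicographically by name so runs are
  deterministic. At most one interaction marker is kept per model.
- A selected marker always enters with both its dichotomized main effect
  and its treatment interaction, and its cut-point posterior is
  recomputed whenever the covariate set changes.

If no interaction crosses the bar, `run_learning` still reports a
threshold — the posterior median of the first candidate marker — but
flags `marker_selected = False` so downstream users can distinguish a
validated predictive marker from a fallback split. The acceptance script
reports this flag at both n = 69 and n = 400: at the historical trial's
size the evidence bar is frequently not crossed, which is the honest
power of an evidence-gated selector at ~60 events.

## Survival engine

Written from scratch (and cross-checked against lifelines and brute-force
risk-set enumeration in the tests):

- Kaplan–Meier with censored-at-event-time records counted at risk for
  that time; Greenwood variance; pointwise CIs and the median CI on the
  log(−log) scale (the "exponential Greenwood" transform, matching the
  common reference implementations). Median convention: smallest `t` with
  `S(t) ≤ 0.5`; an undetermined endpoint is reported as NA.
- Two-sample log-rank with hypergeometric variance. For a single binary
  covariate and tie-free data, the Cox score test at β = 0 equals this
  statistic (asserted to 1e-6 in the suite).
- Cox: Newton–Raphson with step halving, convergence when the relative
  change in partial log-likelihood < 1e-9 (cap 25 iterations); SEs from
  the inverse observed information; Wald CIs exponentiated. Efron ties
  everywhere — month-granularity survival data tie routinely, and the
  cross-check oracles are configured identically. A coefficient escaping
  |β| > 50 raises a divergence error naming the term (monotone
  likelihood/perfect separation); a design that is constant or collinear
  on the risk sets raises a rank error naming the culprits. A singular
  information matrix at the optimum (flat direction in a tiny stratum)
  falls back to the pseudo-inverse so the fit remains reportable.

## Synthetic trials

The generator emulates the structure the analysis assumes, not any real
dataset:

- Markers: log-normal on the raw scale (log-mean 4.1, log-sd 0.75),
  clipped to (0.5, 255] — right-skewed scores needing the log2 transform,
  on the bounded assay scale. ERCC1 and RRM1 are drawn independently;
  real assays correlate them, which makes the synthetic selection problem
  slightly *easier* for distinguishing the two markers than reality.
- Latent threshold `c*`: a quantile (default 0.21) of the realized ERCC1
  scores, defined on the **raw** scale so that learning on standardized
  scores exercises the full preprocessing path.
- Survival: exponential baseline (0.07/month ⇒ ~10-month median),
  proportional effects for age/sex/histology, and a treatment log-HR that
  switches at `c*` (defaults HR 0.6 below, 1.25 above — benefit flips to
  mild harm). The hazard-modifying "treatment" is carboplatin exposure:
  the experimental arm in the single-agent-control design (G vs GC), a
  GC/DC regimen in the marker-directed design, whose control arm also
  receives GC by design.
- Censoring: independent exponential (0.01/month) plus administrative
  cut-off at 48 months — the standard non-informative mechanism of a
  trial with fixed accrual.
- Randomization is iid Bernoulli at the allocation ratio (default 2:1);
  covariates: age ~ N(64, 9²) truncated to [35, 90], sex balanced,
  histology (0.53, 0.18, 0.29), stage IIIB fraction 0.07.
- One `numpy` Generator seeded per dataset; identical config + seed gives
  byte-identical cohorts.

What passing tests therefore do **not** show: robustness to assay batch
effects or calibration drift between cohorts, correlated markers,
non-exponential baselines, informative censoring, or missing covariate
data. The per-cohort standardization is the package's (and the method's)
answer to between-trial assay drift, but the generator does not simulate
the drift itself.

## Problem sizes in the checked experiments

The simulation suites run at the sizes where the method's operating
characteristics were established: threshold recovery uses 50 replicates
of n = 400 (HR 0.5/1.5 across a threshold at the 30th marker percentile)
and requires the posterior-median cut-point within ±0.25 standardized
units of truth in ≥ 80% of replicates with the interaction selected in
≥ 90%; false-positive control uses 100 null replicates of n = 300 with an
interaction admitted in ≤ 10% and uniform log-rank p-values. The
acceptance script additionally runs the pipeline once at the historical
cohort sizes (n = 69 learning, n = 275 validation, 2:1).

## Known limitations

- The cut-point posterior treats the profiled partial likelihood as a
  likelihood; it has no formal Bayesian coverage guarantee, and the 95%
  credible interval should be read as a likelihood-support interval.
- Only one interaction marker per model; no spike-and-slab or full MCMC
  selection; no time-varying coefficients; no stratified Cox, sandwich
  variances or proportional-hazards diagnostics.
- Age enters linearly in years; the low-marker carboplatin-vs-other
  contrast is deliberately not computed (by design nearly all low-marker
  patients receive carboplatin, leaving no comparison group).
- Rows with missing fields are not imputed; loaders expect complete
  records.
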