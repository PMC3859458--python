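# cutpointsurv

Outcome-based cut-point selection for a continuous predictive biomarker,
with threshold-stratified survival validation in an independent cohort.

## The problem

In advanced non-small-cell lung cancer, tumoral ERCC1 protein levels
(measured in situ on a bounded 0–255 fluorescence scale) are a candidate
*predictive* biomarker for platinum-based chemotherapy: patients with low
ERCC1 appear to benefit from carboplatin-containing regimens while
patients with high ERCC1 do not. Turning a continuous, right-skewed assay
readout into a treatment rule requires (i) a threshold that is learned
from survival outcomes rather than picked at the median, and (ii) honest
validation of that frozen threshold in an independent randomized trial.
This package implements that full workflow for biostatisticians working
with patient-level trial data, together with a synthetic-trial generator
so every stage is testable without access to the original cohorts.

## The method

Marker scores `m` are log2-transformed and robustly standardized within
each cohort,

    z = (log2 m − median) / (1.4826 · MAD),

so a threshold is a *scaled distance from each trial's own median*. For a
candidate cut-point `c`, survival is modeled by a Cox proportional-hazards
model with an Efron-ties partial likelihood

    h(t|x) = h0(t) · exp( β₁·treat + βᵀz + γ₁·1{z ≥ c} + γ₂·treat·1{z ≥ c} ),

and the profile partial log-likelihood `ℓ*(c)` is computed over a grid of
observed marker values. With a uniform prior over the grid, the
(pseudo-)posterior over cut-points is `π(c) ∝ exp ℓ*(c)`; its weighted
median is the operational threshold and its central 95% interval the
credible band. Variable selection alternates a *screen* phase (rank
candidate treatment-interacting markers and prognostic covariates by
BIC-approximated log Bayes factors; admit the best one exceeding log BF =
3) with a *build* phase (refit jointly, drop terms whose evidence falls
below the bar) until a fixed point — so a marker is declared predictive
only when the evidence survives adjustment for prognostic structure, and
the false-positive rate is controlled.

The frozen threshold then stratifies an independent cohort into high/low
groups, compared by Kaplan–Meier curves (Greenwood variance,
Brookmeyer–Crowley median CIs), the two-sample log-rank test, and Cox
models adjusted for age, sex and histology. Cohort-composition questions
use Fisher's exact, exact McNemar and Wilcoxon rank-sum tests.

All survival machinery (KM, log-rank, Efron-ties Newton–Raphson Cox) is
implemented in this package and cross-checked in the test suite against
lifelines and brute-force risk-set enumeration.

## Worked example

Simulate a learning trial (1:1, single-agent control vs carboplatin
doublet; carboplatin HR 0.5 below the latent threshold, 1.5 above) and a
marker-directed validation trial, then learn, freeze and validate.
The two configs:

```yaml
# learn_cfg.yaml                      # valid_cfg.yaml differs only in:
n_patients: 400                       #   n_patients: 275
allocation_ratio: [1, 1]              #   allocation_ratio: [2, 1]
regimen_scheme: single-agent-control  #   regimen_scheme: marker-directed
true_cutpoint_quantile: 0.3           #   seed: 6
log_hr_treatment_low: -0.693
log_hr_treatment_high: 0.405
frac_stage_iiib: 0.05
seed: 5
```

```bash
cutpointsurv simulate --config learn_cfg.yaml --out learn.csv
cutpointsurv simulate --config valid_cfg.yaml --out valid.csv
cutpointsurv -v learn --data learn.csv --out learn_result.json
cutpointsurv validate --data valid.csv --learn learn_result.json \
    --grouping pooled-gc --out report.json
cutpointsurv report --in report.json --format md
```

Output of the final command with these configs:

```
# Validation report — pooled-gc

Threshold (standardized): -0.4699 on `ercc1_std`
Cohort n = 266 (high 190, low 76)

| group | n | events | median OS | 95% CI |
|---|---|---|---|---|
| high | 91 | 80 | 5.1 | 3.7 to 7.4 |
| low | 56 | 41 | 17.7 | 11.3 to 28.0 |

Log-rank: chi2 = 27.162, p = 1.871e-07
Adjusted Cox (low_marker): HR = 0.352 (95% CI 0.235 to 0.527; p = 3.987e-07)
```

Reading: the learning stage recovered a standardized threshold of −0.47
(the generative truth for that seed is the 30th marker percentile,
z ≈ −0.52); among validation-cohort patients who received
gemcitabine/carboplatin, marker-low patients lived markedly longer
(median 17.7 vs 5.1 months), and the age/sex/histology-adjusted hazard
ratio for low vs high is 0.35 — the low group benefits, the high group
does not. The same classes are available directly in Python
(`MarkerStandardizer`, `CutpointSelector`, `CoxPHRegressor` follow the
scikit-learn fit/transform/predict idiom), with `run_learning` /
`run_validation` as the one-call pipeline surface.

The equivalent count tests are exposed on the CLI too, e.g.

```bash
cutpointsurv fisher --a 59 --b 24 --c 143 --d 30
# {"statistic": 0.5157..., "p_value": 0.0487..., "method": "fisher-exact"}
```

## Layout

- `src/cutpointsurv/simulate.py` — synthetic randomized-trial generator
- `src/cutpointsurv/preprocess.py` — log2 + median/MAD standardization, thresholding, stage filter
- `src/cutpointsurv/cutpoint.py` — profile likelihood, cut-point posterior, screen/build selection
- `src/cutpointsurv/survival.py` — Kaplan–Meier, log-rank, Efron-ties Cox regression
- `src/cutpointsurv/assoc.py` — Fisher / McNemar / rank-sum tests
- `src/cutpointsurv/pipeline.py` — learn-then-validate orchestration
- `docs/methods.md` — modeling assumptions, defaults and limitations
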