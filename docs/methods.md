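# Methods

`dcdliver` implements the statistical machinery for studying how donor
time to death (TTD) — the interval from withdrawal of life-sustaining
treatment (WLST) to asystole in controlled donation after circulatory
death (DCD) — relates to liver utilization and post-transplant outcomes,
and for quantifying how many additional livers would be accepted if offers
from prolonged-TTD donors were evaluated like short-TTD offers. Real donor
registries are not redistributable, so the package ships a synthetic
registry generator whose generating truth is known analytically; every
downstream stage is validated against that truth.

## Cohort definitions

Warm-ischemia intervals are derived in minutes: TTD = asystole − WLST;
asystolic time = cold flush − asystole; functional TTD (FTTD) = cold flush −
time of first systolic blood pressure <50 mm Hg. As printed in the source
definitions FTTD runs to cold flush and therefore subsumes the asystolic
period; `CohortSpec(fttd_end="asystole")` switches to the stricter reading.
Recovery pathway is inferred from asystolic time: >30 min ⇒ normothermic
regional perfusion (NRP), ≤30 min (boundary included) ⇒ super-rapid
recovery (SRR). Exclusions (uncontrolled DCD, missing TTD/asystolic time,
date window; pediatric recipients and multi-organ transplants on the
outcome side) are applied in a fixed order and logged so counts reconcile
with cohort sizes. Length of stay is analyzed as time-to-discharge with
discharge the event, censored at 90 days and at death/graft loss before
discharge. TTD strata are half-open `[lo, hi)` with shared boundaries
assigned to the upper stratum (configurable edge list, default
0/10/15/30/45/∞); donors with TTD = 0 are retained.

## Restricted cubic splines

Continuous exposures with suspected nonlinearity enter models as
restricted cubic splines with k = 4 knots at the 5th/35th/65th/95th sample
percentiles (linear-interpolation quantiles), computed once per analysis
cohort and frozen across imputations so pooled coefficients are
commensurable. The basis is the truncated-power natural spline: the linear
term plus k−2 nonlinear terms, each divided by `(t_k − t_1)²` so all
coefficients live on the predictor's scale (the dominant convention of the
R `rms` toolchain). The implied function is linear beyond the boundary
knots with continuous value, first and second derivatives. Spline blocks
are tested jointly with a chi-square Wald statistic `β'V⁻¹β` on the pooled
coefficients and covariance. Effect curves relative to a reference value
`x_ref` (default: the first knot) use the contrast
`basis(x) − basis(x_ref)` with delta-method pointwise 95% bands; grid
points beyond the 1st–99th percentile of the training data are flagged as
extrapolation but never withheld.

## Multiple imputation

Missing covariates are imputed by predictive mean matching (PMM) with
bootstrap resampling: per imputation and per target variable, an additive
linear model with RCS terms (3 internal knots) for continuous predictors
is fit on a bootstrap resample of the records observed for that variable;
each missing entry receives the observed value of a donor drawn at random
among the `k_pmm = 3` records with the closest predictions, so imputations
always lie in the observed support and nonlinear covariate relationships
survive. Outcome information is carried into the imputation model through
auxiliaries — the event indicator and the Nelson–Aalen cumulative hazard
for survival outcomes, the utilization flag for acceptance models. The two
primary exposures (TTD, asystolic time) are never imputed; donors missing
them are excluded. This is a deliberately simplified analog of
`aregImpute`-style flexible PMM: no canonical-variate transformation, no
optimal scaling of categoricals (categorical targets are matched on an
integer-coded score and inherit the matched donor's category), and
co-missing variables are imputed independently given the fully observed
predictors rather than by chained passes. m = 20 imputations by default.

Pooling follows Rubin's rules: pooled coefficients are means; total
covariance is `W + (1 + 1/m)B` with `W` the mean within-imputation
covariance and `B` the between-imputation sample covariance. Wald tests
(including spline-block tests) are computed single-step on the pooled
quantities with a large-sample chi-square reference — at registry scale
the small-sample degrees-of-freedom corrections and D1/D2 multivariate
pooling variants are immaterial, but this is a documented limitation for
small n.

## Outcome and utilization models

Graft survival (graft loss or death), patient survival and time-to-
discharge are Cox proportional-hazards models (Efron tie handling —
registry times are day-granular and tie heavily); early graft loss
(within 30 days) and utilization are logistic. One- vs five-year analyses
administratively truncate follow-up at the horizon. Right-skewed
covariates not splined are log2-transformed (effects per doubling); a
nonpositive value under log2 is a hard error with an explicit opt-in
offset, because silently shifting zeros changes the estimand. Categorical
covariates are dummy-coded against a stated reference; interactions are
element-wise products of encoded blocks. Center-level frailty terms are
out of scope. Any fit failure on an imputed dataset aborts the pooled
analysis with the dataset index — datasets are never silently dropped.

## Counterfactual standardization ("extra livers")

Within the reference stratum (TTD < 10 min, where TTD does not drive
acceptance), a logistic utilization model excluding TTD is fit; applying
it to each donor in a target stratum (15–30 or 30–45 min) and averaging
the predicted probabilities gives the counterfactual acceptance rate under
reference-stratum decision-making (G-computation). Reported quantities:
absolute increase (percentage points), relative increase (% of the actual
rate), and extra organs `n_target × (predicted − actual)`. Confidence
intervals are percentile bootstrap: strata are resampled independently
with replacement (a joint-resampling variant is available), the reference
model is refit per replicate, and the 2.5th/97.5th percentiles of each
replicate statistic form the 95% interval; 10 000 replicates by default.

Replicate refits use an in-package Newton/IRLS solver on a design matrix
encoded once up front. Freezing the encoding means a resampled target can
never contain a level unseen by the encoder; a level absent from a
resampled *reference* stratum yields an all-zero column whose coefficient
a small ridge pins at zero, i.e. those target donors are projected with
the reference-level effect. Refits that separate on a rare dummy level are
kept with coefficients capped at |β| = 30 on the standardized scale
(boundary fitted probabilities are valid for standardization); only
one-class resamples count as degenerate, and more than 5% degenerate
replicates escalates to an error. When imputation is in play the point
estimate is computed on a designated completed dataset by default; nesting
the full imputation loop inside the bootstrap is supported but off by
default for cost.

## Synthetic registry and its analytic oracle

The generator emulates the study conditions of a national DCD liver
registry:

| quantity | default | rationale |
|---|---|---|
| TTD | log-normal, median 13 min, IQR 9–17 | matches the reported registry summaries |
| asystolic time | log-normal; SRR median 14 min (σ=0.45), NRP median 48 (σ=0.25) | plausibility only; keeps pathways mostly on their side of the 30-min rule |
| NRP fraction | 0.10 | ~10% of recent registry donors |
| utilization logit | flat at −0.4 for TTD ≤ 15 min, −2.4 logits linearly over 15–45 min, flat after | qualitative "cliff" in acceptance past 15 min; gives ~40%/~32%/~13% acceptance in the <10/15–30/30–45 strata |
| graft hazard | exponential, ~88% 1-y survival; short-TTD log-hazard penalty 0.5·max(0,(12−TTD)/12) | excess injury of near-instant-death donors fading by ~12 min, a range a 4-knot spline can resolve |
| covariate effects | age −0.02/y, BMI −0.045/unit, peak ALT −0.10 per doubling on the acceptance logit | modest, realistic directions; skewed labs are log-normal so log2 modeling is well-specified |
| missingness | MAR, 1–5% per variable, tilted by always-observed variables | registry-like; the exposures are never blanked |
| censoring | 10% uniform administrative censoring within a 5-y horizon | emulates a minimum-follow-up design |

`TruthSummary` and `true_counterfactual` are computed analytically from the
configuration — Gauss–Hermite/Bernoulli tensor quadrature over the
covariate distribution and Gauss–Legendre quadrature over the TTD density —
never from sampled data, so they are seed-invariant oracles. The
counterfactual truth replaces the TTD logit term with the population limit
of the reference-stratum intercept (exact when the logit is flat on the
reference stratum, root-found otherwise). Utilization draws use a dedicated
random substream, so configurations differing only in the decline share all
other draws (common random numbers), which makes the monotonicity of the
estimated extra organs in the injected decline exact rather than
statistical.

What the generator does **not** emulate: the joint covariate distribution
of real donors, organ-offer sequencing, center-level clustering, and any
pathway-specific utilization behavior (the same TTD curve applies to SRR
and NRP donors; counterfactual analyses are run on the SRR cohort). Tests
passing on synthetic data therefore demonstrate the estimators' internal
validity — calibration, parameter recovery, invariances — not the
clinical conclusions themselves.

## Table schema

Donor and transplant tables are comma-separated text with a header row;
times are numeric minutes (or an ISO-8601 `wlst_time`/`asystole_time`/
`flush_time` triple from which `derive_times` computes them). Required
donor columns: `donor_id`, `ttd_min`, `asystolic_min`, `utilized` (0/1);
recognized optional columns include `sbp50_to_asystole_min`, donor
covariates (`donor_age`, `donor_bmi`, `donor_sex`, `cause_of_death`,
`hypertension`, `diabetes`, `blood_group`, `peak_alt`, `peak_bilirubin`,
`peak_albumin`, `peak_sodium`, `donation_year`) and the `uncontrolled`
exclusion flag. Required transplant columns: `donor_id`, `recipient_age`,
`graft_time_days`/`graft_event`, `patient_time_days`/`patient_event`,
`los_days`/`discharged`; recipient covariates follow the generator's
naming (`meld`, `diagnosis`, `dialysis`, `recipient_diabetes`, `status1a`,
`medical_condition`, `functional_status`, `ethnicity`, `waitlist_days`,
`cold_ischemic_hours`, `machine_perfusion`). `read_donor_table` /
`read_transplant_table` validate required columns on read.

## Numerical choices and degenerate inputs

Knot ties raise an error suggesting fewer knots; constant covariates and
one-class outcomes are hard errors naming the column; singular Wald
submatrices report the aliased eigendirections; all-censored input is a
valid Nelson–Aalen case (H ≡ 0). Extra-organ counts are reported unrounded
and rounded (half-up, stated in the output). All randomness flows from one
global seed through named `SeedSequence` substreams per stage
(generate/missingness/impute/bootstrap), recorded in the run manifest, so
stages are independently reproducible and a rerun is bit-identical.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) runs the pipeline at
20 000 donors with 10 imputations and 2 000 bootstrap replicates per
stratum — large enough that the standardized estimates sit within a few
percent of the analytic truth. The simulation-calibration tests use 200
replicate registries of 3 000 donors with 500 bootstrap replicates each,
the scale at which coverage statements (90–99%) are sharp enough to detect
real miscalibration.
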