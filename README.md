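# dcdliver

Statistical pipeline for studying donor **time to death (TTD)** in
controlled donation-after-circulatory-death (DCD) liver transplantation:
does prolonged TTD actually harm outcomes, and how many livers are being
declined for no good reason because of it?

After withdrawal of life-sustaining treatment (WLST), donor warm ischemia
splits into two physiologically distinct intervals: TTD (WLST → asystole,
with some residual perfusion) and asystolic time (asystole → aortic cold
flush, with none). `dcdliver` provides, for registry-style donor and
transplant tables:

- **Cohort assembly** — derived warm-ischemia intervals, the 30-minute
  asystole-to-flush rule separating super-rapid recovery (SRR) from
  normothermic regional perfusion (NRP), inclusion/exclusion with an
  audited log, 90-day length-of-stay censoring, half-open TTD strata.
- **Nonlinear models under multiple imputation** — Cox (graft survival,
  patient survival, time-to-discharge) and logistic (early graft loss,
  utilization) regression with restricted cubic splines (4 knots at the
  5/35/65/95th percentiles), log2-transformed skewed labs, interactions;
  predictive-mean-matching imputation (m = 20) with outcome auxiliaries
  (event indicator + Nelson–Aalen cumulative hazard) and Rubin's-rules
  pooling; joint spline Wald tests and delta-method effect curves.
- **Counterfactual "extra livers" simulation** — G-computation: fit a
  TTD-free utilization model on the reference stratum (TTD < 10 min),
  project it onto the 15–30 and 30–45 min strata, and report the absolute
  and relative acceptance increase and the extra-organ count
  `n_target · (predicted − actual)`, with 95% percentile-bootstrap
  confidence intervals (10 000 replicates).
- **A synthetic registry generator** with analytically known truth
  (acceptance logits, survival hazards, MAR missingness), so every stage
  has a parameter-recovery oracle without access to any real registry.

The core counterfactual quantity, for target stratum `T` and reference
model `π̂(x)` fit on donors with TTD < 10 min excluding TTD itself:

```
predicted rate  p̄ = (1/n_T) Σ_{i∈T} π̂(x_i)
extra organs       = n_T · (p̄ − ȳ_T),   ȳ_T the observed acceptance rate
```

## Worked example

```python
from dcdliver import GeneratorConfig, generate_registry, true_counterfactual
from dcdliver.counterfactual import CounterfactualSpec, bootstrap_ci
from dcdliver.models import ModelSpec, Term

config = GeneratorConfig(n_donors=10_000, seed=7)
donors, transplants, truth = generate_registry(config)

model = ModelSpec(
    name="utilization", outcome_type="binary", outcome="utilized",
    terms=(Term("donor_age"), Term("donor_bmi"), Term("peak_alt", kind="log2")),
)
spec = CounterfactualSpec(model=model, reference=(0, 10), target=(15, 30),
                          reps=2000, seed=7)
res = bootstrap_ci(donors, spec)
```

prints (via the obvious f-strings):

```
10000 donors, 3659 transplants; acceptance 36.6%
actual acceptance (TTD 15-30): 31.7%
predicted under <10-min decision-making: 40.9% (39.0-42.7)
extra livers: 307 (95% CI 231-388)
analytic truth: 289
```

Reading: under the generator's default conditions (acceptance logit flat
below 15 min, dropping 2.4 logits by 45 min), donors dying 15–30 min after
withdrawal had 31.7% of their livers accepted; had those offers been
judged like <10-min offers they would have reached 40.9%, i.e. ~307 extra
transplants — and the generator's analytic expected value, 289, falls
inside the bootstrap interval.

The same analysis end-to-end (simulate → assemble → impute → fit →
counterfactual) from the shell:

```bash
dcdliver run-all --n-donors 5000 --seed 1 --reps 2000 --out run1
dcdliver counterfactual --table run1/registry/donors.csv \
    --reference "<10" --target "30-45" --reps 10000 --seed 2 --out cf.json
```

`run-all` writes a manifest (seeds, cohort sizes, exclusion counts),
pooled model tables, TTD effect curves, Kaplan–Meier data and the
counterfactual JSON into the output directory.

## Layout

```
src/dcdliver/
  registry.py        synthetic donor/transplant generator + analytic oracle
  cohort.py          derived times, SRR/NRP rule, exclusions, LOS censoring
  splines.py         restricted cubic splines, Wald tests, effect curves
  impute.py          PMM multiple imputation, Nelson–Aalen, Rubin pooling
  models.py          Cox/logistic fitting, encoding, KM, pooled MI analysis
  counterfactual.py  standardization + percentile bootstrap
  pipeline.py        run orchestration, manifests, table rendering
  cli.py             `dcdliver` command group
  configs/           default model covariate lists (YAML)
docs/methods.md      model, generator and design documentation
```
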