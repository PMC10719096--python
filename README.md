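# radcohort

Simulation and dose–response modelling of hematological-malignancy risk in
cohorts of children and young adults exposed to CT radiation.

Registry-linked CT cohorts ask a precise question: per mGy of cumulative
absorbed dose to the active bone marrow (ABM), how much does the incidence
rate of leukemia and lymphoma rise?  The canonical answer is a linear
excess-relative-risk model on the attained-age time scale,

    rate(t) = λ₀(t; sex, country, birth cohort) · (1 + β · Z(t − lag))

where `Z` is the lagged cumulative ABM dose and `β` is the ERR per unit
dose (conventionally reported per 100 mGy), complemented by an additive
excess-absolute-risk (EAR) model on person-year tables,

    rate = λ_bg(stratum) + α · Z

with `α` the excess cases per person-year per mGy.  `radcohort` implements
both, with the surrounding machinery such a study needs: a validated
cohort data model (persons / examinations / outcomes / morphology→endpoint
mapping), Monte-Carlo per-exam dose ensembles with shared and unshared
uncertainty components, stratified risk sets with profile-likelihood CIs,
categorical RRs with trend tests, effect-modification LRTs, a full
sensitivity suite (alternative lags, dose percentile truncation, exclusion
windows, leave-one-country-out, …), and — because real registry data of
this kind are not freely available — a seeded synthetic-cohort generator
with known ground truth for every downstream stage.

Intended users: radiation epidemiologists and biostatisticians who want a
tested, scriptable implementation of these models, and methodologists who
need a realistic cohort test bed.

## Worked example

Simulate a cohort with known truth (ERR/100 mGy = 2.0, 2-year lag), build
risk sets, and fit:

```python
from radcohort import (SimulationConfig, simulate_cohort,
                       build_risk_sets, fit_linear_err, fit_categorical_rr)
from radcohort.synthetic_cohort import BaselineHazard

cfg = SimulationConfig(n_persons=25_000, seed=42, n_realizations=1,
                       baseline_hazard=BaselineHazard().scaled(25),
                       true_beta=0.02)          # true ERR/100 mGy = 2.0
sim = simulate_cohort(cfg)
rs = build_risk_sets(sim.cohort, endpoint="all_heme", lag=2.0)
fit = fit_linear_err(rs)
print(f"ERR/100 mGy = {fit.err_per_100:.2f} "
      f"(95% CI {fit.ci_per_100[0]:.2f} to {fit.ci_per_100[1]:.2f})")
```

prints

```
ERR/100 mGy = 1.10 (95% CI 0.29 to 2.18)
```

590 simulated cases; the profile CI comfortably covers the generating
value 2.0 (single-cohort estimates at this case count are noisy — the
bias/coverage behaviour is quantified over 100 replicates in the test
suite).  The categorical fit on the same risk sets,

```python
cat = fit_categorical_rr(rs)
```

gives the dose-category table (reference `[0,5)` mGy, Wald CIs):

```
[0,5)    n=179  RR=1.00
[5,10)   n=148  RR=1.01 (0.81-1.25)
[10,15)  n=87   RR=1.08 (0.84-1.40)
[15,25)  n=101  RR=1.41 (1.11-1.81)
[25,50)  n=52   RR=1.11 (0.82-1.52)
[50+]    n=23   RR=1.85 (1.20-2.87)
trend p = 0.0043
```

— a rising gradient with a clearly significant trend, as expected under a
positive generating slope.

The same pipeline is scriptable from the shell:

```bash
radcohort simulate --n 20000 --seed 7 --out data
radcohort prepare  --data data --out prepared
radcohort fit-err  --data prepared
radcohort report   --data prepared --out results --with-sensitivity
```

`report` writes tidy CSVs (continuous, categorical, trend, heterogeneity,
EAR, sensitivity grid), an exclusion log and a human-readable summary.

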