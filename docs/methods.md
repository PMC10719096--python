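# Methods

## The problem

Cohorts of children and young adults who underwent CT examinations are
followed through cancer registries to quantify the risk of hematological
malignancies per unit of cumulative absorbed dose to the active bone
marrow (ABM).  The package implements the full analysis chain for such a
study — cohort data model, dose metrics, risk models, sensitivity suite —
together with a synthetic-cohort generator that reproduces the statistical
structure of the design, so that every stage can be exercised and
validated without access to confidential registry data.

## Risk models

**Linear excess relative risk (ERR).**  The incidence rate at attained age
`t` is modelled as

    rate(t) = lambda0(t; stratum) * (1 + beta * Z(t - lag))

with `Z` the cumulative lagged ABM dose (mGy) and strata defined by sex ×
country × birth cohort (bins 1960–1979, 1980–1984, …, 2005–2012).  The
baseline `lambda0` is eliminated by the stratified partial likelihood: at
each case's exact diagnosis age the case's relative risk is compared with
the sum over all stratum members at risk (entry < t ≤ exit; half-open
at-risk windows, an event at exactly the exit age belongs to the interval).
`beta` (reported ×100 as ERR/100 mGy) is found by bounded one-dimensional
search on the admissible interval `(-1/max Z, 1e4)`; the 95% CI is
profile-likelihood based (deviance ≤ 3.841), found by bisection on each
side, with a boundary flag when an endpoint hits the admissible edge.
Categorical dose effects (cutpoints 5, 10, 15, 25, 50 mGy, half-open bins,
lowest bin as reference) use the same partial likelihood with log-linear
category parameters and Wald CIs from the numerically differentiated
observed information; the dose-trend test replaces the indicators by the
category index (category-specific mean dose available as an option) and
refers twice the log-likelihood-ratio to chi-square(1).  Effect
modification by age at exposure (<5, 5–10, ≥10 y), time since exposure
(2–5, 5–10, ≥10 y, floored at the lag), sex or birth cohort is tested by a
likelihood-ratio test of window-specific slopes `1 + sum_m beta_m Z_m`
against a common slope (df = identifiable windows − 1).  Tied event ages
receive Breslow handling; simulated ages are continuous so exact ties have
measure zero.

**Additive excess absolute risk (EAR).**  Follow-up is tabulated exactly
onto person-year cells (attained-age band × sex × country × birth cohort ×
dose stratum), splitting each at-risk window at band edges and dose-step
ages so person-years, case counts and PY-weighted mean doses are exact.
The cell rate is `exp(x'theta) + alpha * mean_dose` with one background
parameter per cross-classified background stratum (age band × sex by
default — crossing, not additive main effects, to mirror the stratified
RR baseline) and `alpha` the excess cases per PY per mGy.  The Poisson
likelihood is maximized by L-BFGS-B with an analytic gradient and a linear
penalty steering the search back when a fitted rate would turn negative,
then polished by Nelder–Mead; `alpha` gets a profile-likelihood CI.
Formatters convert the canonical unit to "per 100,000 (or 10,000) PYs per
100 mGy".  Projection helpers implement the standard arithmetic: percent
increased risk per exam = ERR/100 mGy × dose (in mGy), and expected excess
cases = alpha × dose × n_persons × (years − lag), the lag removing its
length from the at-risk years (so a 12-year horizon with a 2-year lag
contributes 10 excess-risk years).

## Synthetic cohorts

The generator draws, per person: sex (P(male) = 0.56), country (nine
countries with the study's cohort shares), birth year (seven cohort bands),
age at first CT (bands <1, 1–5, 5–10, 10–15, ≥15 y with weights 0.115,
0.17, 0.192, 0.217, 0.306, uniform within band, clipped so examinations
fall in 1977–2014 and below age 22), number of exams (1 + negative
binomial with mean 0.52 and dispersion 0.168, hitting mean ≈ 1.52 and s.d.
≈ 1.46 exams per patient), body regions (head/neck 0.81, chest 0.07,
abdomen/pelvis 0.06, spine 0.03, other 0.03), a hospital within the
country, and non-informative censoring (death rate 3e-4/y; emigration
2.5e-3/y in the three countries that track migration; administrative end
2016).  Registry-start years vary by country so late-entry handling is
exercised.

Per-exam doses come from a geometric-mean table by body region × age band
(0–1, 1–5, 5–10, 10–15, ≥15 y) × period (<1991, 1991–2001, ≥2002) anchored
at the published trend figures (head newborn 15→12 mGy, head adult 2.6;
chest newborn 18→7, chest adult 8→5; intermediate cells interpolated as
plausible pediatric ABM doses).  Uncertainty is a Monte-Carlo ensemble
(default 200 realizations): dose = gm × shared × unshared, both
multiplicative lognormal with median 1 — the shared factor (GSD 1.2) is
identical across exams of the same hospital × period within a realization
index, the unshared factor (GSD 2.0) is independent per exam-realization,
so the total spread is "of the order of 2".

The per-exam *true* dose is defined as the arithmetic mean of the exam's
ensemble, i.e. the analysis metric coincides with the truth.  The ensemble
therefore represents dosimetric uncertainty about a shared central value,
not classical person-level measurement error; attenuation from classical
error (and the resulting downward bias in beta) is deliberately **not**
emulated.  Passing recovery tests consequently show that the estimator is
unbiased when the dose metric is correct, and say nothing about
measurement-error bias in real data.

Events are drawn from `lambda0(t, sex) × (1 + beta Z(t − lag))` with a
piecewise-constant default baseline of order 1e-4 per PY below age 40
(slight male excess).  Both factors are step functions of attained age, so
each person's at-risk window is split into constant-hazard segments (at
age-band edges and exam-age + lag steps) and the event time is obtained by
exact inversion of the cumulative hazard against one Exp(1) draw per
person — no discretization error; the same segment machinery drives the
person-year tabulation.  Simulated cases receive representative ICD-O-3
morphology codes in roughly the published subtype mix so the
outcome-classification plumbing is exercised end to end.

Everything is deterministic given (config, seed); stage-specific
generators are spawned from a seed sequence.

What the generator does *not* emulate: confounding by indication,
dose–exam-count–age dependence beyond the band structure (exam count and
age at first CT are drawn independently), multiple primaries, realistic
hospital networks, registry linkage error, and classical dose error as
noted above.

## Validation protocols and their problem sizes

The test suite runs five simulation studies whose sizes were chosen to put
each asymptotic approximation in its valid regime while keeping the whole
suite at desk scale:

- **Parameter recovery** — 100 cohorts of 200,000 persons with the
  baseline scaled ×1.5 to yield ~300 cases each, true ERR/100 mGy = 2.0,
  lag 2.  Checks mean bias of the ERR (within ±15%) and profile-CI
  coverage (binomial band [89%, 99%] around 95%).
- **Type-I error** — 500 null cohorts (beta = 0) of 12,000 persons with a
  balanced age-at-first-CT mix and ~370 cases each; the balanced mix puts
  exposure into every age window — with the study's own skewed mix the
  constrained window slopes sit near the admissible boundary
  (beta_m ≥ −1/max Z_m) and the chi-square reference is conservative
  (~2.5% rejection).  Checks trend-test and heterogeneity-LRT rejection at
  the 5% level within [3%, 7%].
- **Cox limit** — one 80,000-person cohort at true ERR/100 mGy = 0.1;
  the linear slope agrees within 10% with the log-linear slope from an
  independent stratified Cox fit (lifelines, start-stop episodes).
- **ERR/EAR consistency** — one 60,000-person cohort (~1,500 cases); the
  additive alpha divided by the PY-weighted mean fitted background rate
  reproduces the direct ERR within 25%.
- **Band-refinement invariance** — under a flat baseline (where the
  additive model is exactly correct) halving the age bands moves alpha by
  <2%.  Under the default age-varying multiplicative truth the
  single-alpha additive model is misspecified and refinement shifts alpha
  by a few percent; that is a property of the model, not a defect.

## Numerical choices and degenerate inputs

- Dates are decimal calendar years; ages are exact float differences.
- Dose boundary convention: an exam at age `a` counts toward `Z(t)` iff
  `a ≤ t − lag` (an event exactly `lag` years after an exam sees that
  dose).
- Percentile truncation keeps ties at the threshold (≤), so re-applying
  the same threshold is a no-op; the truncation subsets use the total
  end-of-follow-up cumulative dose.
- Dose categories are time-varying (evaluated at the event age); a person
  migrates upward through categories during follow-up.  An
  end-of-follow-up alternative was considered and rejected as primary
  because the risk-set exposure is itself time-varying.
- Flat likelihoods (no within-stratum exposure variation) return an
  explicit `non_identifiable` status, never a number; empty case sets
  return `no_cases`; empty dose categories are dropped with a warning;
  windows with zero exposure reduce the LRT degrees of freedom.
- Cases with no stratum peers at risk form singleton risk sets that are
  kept (they contribute a constant) and logged with a warning.
- The unknown-morphology route classifies to `unspecified` with a warning
  rather than dropping the case silently; behavior codes other than 3 and
  therapy-related codes yield the empty endpoint set.
- Optimizers are deterministic (no random restarts): bounded Brent for the
  scalar ERR, brentq bisection for profile bounds (deviance solved to
  1e-6), Nelder–Mead for the small-dimension window fits, L-BFGS-B with
  analytic gradients for the EAR background.

## Known limitations

- The additive EAR model with a single alpha is an approximation whenever
  the true excess is multiplicative with an age-varying baseline; the
  implied-ERR conversion uses the PY-weighted mean background rate and is
  accurate to ~10% at realistic case counts.
- Nested case-control subsampling (`control_sample`) uses the plain
  conditional likelihood, valid for uniform sampling of non-cases; no
  weighted estimators for other designs.
- The morphology mapping ships with representative ICD-O-3 code blocks,
  not a registry-complete list; it is a user-editable table.
- No multiplicity adjustment across endpoints (matching standard practice
  in this literature); the report notes this.
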