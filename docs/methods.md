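# Methods

## Model

The analysis estimates the mean lifespan of red blood cells created before
the start of CDK4/6-inhibitor therapy from the drift of routine CBC indices
(MCV, MCHC, RBC count) as the pre-treatment cell population is replaced.

**Replacement kinetics.** The residual lifetime of a pre-treatment ("old")
RBC is LogNormal on the day scale. The surviving old fraction at time *t*
days after the first dose is `S(t) = 1 − Φ((log t − μ_s)/σ_s)`; before the
first dose the old fraction is exactly 1. The literature sometimes writes
the standardized argument with a "+" sign (a re-parameterization with a
negated location); this package uses the standard form `(log t − μ_s)/σ_s`
throughout, which is the convention under which the mean lifespan is
`exp(μ_s + σ_s²/2)` — the headline quantity, ≈118 days in healthy adults.
(An alternative definition, the time to replace 95% of the old cells, is a
quantile of the same law and is not used here.)

**Observation model.** Each observable at each draw is a Student-T around
the mixture mean of the patient's old/new true values. Student-T noise (one
scale σ_X and one degrees-of-freedom ν_X per observable, shared across
patients) absorbs the sporadic outliers routine laboratory data contain; a
Normal noise model understates them. Patient-level true values are
hierarchically Normal around population means — 12 hyper-parameters (mean
and SD for old/new × three indices).

**Derived quantities**, computed per posterior draw, never from summaries:
pre/post contrasts of the population means, and hemoglobin through the
hematology identity `Hgb (g/dL) = N_RBC (10^12/L) × MCV (fL) × MCHC (g/dL)
/ 1000`. Hemoglobin is deliberately *not* an independent likelihood term:
it is fully determined by the three modelled indices, and modelling it
separately would double-count the same measurement.

**Units.** Time in days (t = 0 at first dose, negative before), RBC count
in 10^12/L, MCV in fL, MCHC and hemoglobin in g/dL, reported durations in
months at 30.44 days/month.

## Priors

All priors live in one block (`PriorConfig`). They were the least
constrained design choice, since the motivating analysis published no prior
table:

| parameter | prior | rationale |
|---|---|---|
| μ_s | Normal(log 118, 0.3) | anchored to the directly measured healthy lifespan |
| σ_s | LogNormal(log 0.3, 0.5) | centered at the measured healthy lifespan dispersion; keeps the sampler out of the degenerate large-dispersion regime where the survival curve flattens to ≈1/2 at all observed times and the mean lifespan is unidentified (a Half-Normal(0.5) alternative is available) |
| hierarchy means | Normal at physiologic values (RBC 4.5, MCV 90, MCHC 33) with broad SDs (1 / 10 / 3) | centers the scale, dominated by data |
| hierarchy and noise SDs | Half-Normal (scales of a few measurement units) | standard weakly-informative choice |
| ν_X − 1 | Gamma(2, 0.1) | keeps ν > 1 (finite location), allows heavy tails, mass near 10–30 |

A prior-predictive check (in the test suite) confirms simulated MCV
measurements fall overwhelmingly in 60–130 fL. The prior-sensitivity
harness (deliberately overconfident wrong survival prior) demonstrably
biases the lifespan posterior, so informative priors here are a real
modelling commitment, not decoration.

## Posterior computation

The unconstrained posterior (non-centered patient effects, log-transformed
scales, log(ν−1) for degrees of freedom; 20 + 6P dimensions for P patients)
is sampled with an in-package No-U-Turn sampler: leapfrog integration with
a diagonal mass matrix, recursive tree doubling with the u-turn criterion,
divergence flagged at 1000 nats of Hamiltonian error, dual-averaging step
size targeting 0.9 acceptance, and Stan-style windowed variance estimation
for the metric during warmup. Gradients of the log posterior are derived
analytically and verified against central finite differences in the tests;
the sampler itself is validated on closed-form targets (correlated
Gaussians, badly scaled Gaussians, Student-T quantiles).

Default configuration is 4 chains × (2000 warmup + 2000 kept) draws.
The packaged recovery runs use 2 chains × (1000 + 1000) on the 122-patient
cohort, which reproduces the generating parameters comfortably while
keeping a single-core run in the minutes range; convergence acceptance is
0 divergences, split-R̂ < 1.01 and bulk-ESS > 400 per population parameter
(at the reduced draw budget the R̂/ESS thresholds are demanding; the
recovery checks therefore gate on divergences and interval coverage, and
the full default configuration is recommended for production runs).

Model criticism follows the standard battery: per-chain rank-histogram
uniformity (chi-square score), posterior predictive density overlays
(shared rule-of-thumb KDE bandwidth taken from the observed data), and
PSIS-LOO with the pointwise unit being one blood draw — the three
observables' log likelihoods summed — so Pareto k̂ > 0.7 flags an
influential laboratory measurement and k̂ > 1 a severe outlier. A
per-observable pointwise unit is available as an option.

## Synthetic cohort generator

The generator emulates the study conditions of the motivating cohort and is
the package's test bed:

* **122 patients**; treatment duration LogNormal in months with location
  log 7.2 and scale 1.011. The scale is solved from the quartiles 3.4 and
  13.3 months; the three published quantiles are mutually inconsistent for
  a two-parameter law, so the median is matched exactly and the IQR to
  within ~12%. Durations are truncated at 5 years of follow-up.
* **Schedule:** one baseline draw uniform in [−28, 0) days, draws every 14
  days through day 56, then every 28 days while on drug. This emergently
  yields ≈15 CBCs per patient on average (the reference cohort reported a
  mean of 16 — within the spread the published duration quantiles allow).
* **Indices:** pre/post population means 87.8/100.2 fL (MCV),
  33.0/33.69 g/dL (MCHC), 4.50/3.73 ×10^12/L (RBC count); patient-level
  SDs 4.5 fL, 1.0 g/dL, 0.45 ×10^12/L — physiologic inter-patient spreads
  consistent with the reference posterior interval widths. Observation
  noise σ = 1.5 fL / 0.6 g/dL / 0.15 ×10^12/L with ν = 5: routine-analyzer
  magnitudes with occasional outliers; these four constants are free
  calibration choices (unreported upstream) and are overridable.
* **Survival:** σ_s = 0.3 with μ_s set so the mean lifespan is exactly
  118 days (the LogNormal then has an SD of ≈36 days across cells, a
  realistic within-person dispersion).
* Student-T draws are redrawn until positive (measured CBC values are
  physically positive); ground truth (patient values, durations) is emitted
  alongside the records so recovery tests never re-derive it.

**A consistency note on the calibrated contrasts.** With the hemoglobin
identity, the calibrated index shifts (MCV +12.4 fL endpoint difference,
MCHC +0.69 g/dL, RBC −0.77 ×10^12/L) imply a hemoglobin *decrease* of
≈0.45 g/dL at the physiologic 4.5 ×10^12/L baseline. A simultaneous
hemoglobin *rise* of +0.64 g/dL would require an unphysiologic baseline
RBC count near 6.8 ×10^12/L, so the reported-rise figure cannot be
reproduced by any generator consistent with the three index shifts; the
package reports the identity-derived value. Likewise a +12.6 fL MCV shift
is not exactly the difference of the 87.8 and 100.2 fL endpoints (12.4 fL);
the endpoints are taken as authoritative.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: dose reductions and treatment
interruptions (durations are single continuous episodes), neutropenia-driven
scheduling changes, intra-patient drift of the true indices (e.g. iron
status, disease progression), informative dropout, laboratory batch
effects, and any deviation of the true survival law from LogNormal. Tests
establish that *if* the data follow the assumed generative process, the
pipeline recovers its parameters; model criticism (PPC, LOO) is the tool
for judging real data against those assumptions.

## Eligibility rules

From the study design: known start date; ≥5 CBCs in the analysis window;
baseline MCV ≤ 98 fL (strictly greater excludes, since high baseline MCV
suggests a concurrent RBC disorder); records kept from 28 days before the
first dose to the end of the first continuous treatment episode. Continuity
breaks at any ≥30-day dispensing gap; an episode ends one 28-day cycle
after its last dispensing (a dispensing covers a forward interval). Without
dispensing data the last CBC time stands in for the episode end. "Baseline
MCV" is the most recent measurement at t ≤ 0 within the window; with no
pre-treatment draw, the earliest on-treatment draw within 14 days is used,
else the patient is excluded as having no baseline. Exclusion reasons are
machine-readable, one primary reason per patient, evaluated in the order
no-baseline → insufficient count → baseline macrocytosis.

Under the default generator ~10–15% of patients are excluded, almost all
for short treatment durations (<56 days cannot yield 5 draws); truncating
the duration law to avoid this would inflate the median duration by ~12%,
so the exclusions are accepted and documented instead.

## Numerical choices and degenerate inputs

* `S(t)` uses the complementary normal CDF (`ndtr(−z)`) for tail stability;
  at extreme arguments it saturates at exactly 0/1 in floating point.
* σ = 0 observation noise is honored by the generator (returns the mixture
  mean exactly) — used by the noise-free mode that reproduces the textbook
  single-patient MCV trajectory.
* Unusable sampler points (overflowing log-scale coordinates, non-finite
  gradients) evaluate to −∞ log density and are rejected as divergent
  transitions rather than propagating NaNs.
* Duplicate (patient, time) rows keep the first occurrence; the dropped
  count is logged.
* Ties at the baseline-MCV threshold: 98.0 fL is included (strict
  inequality excludes).
* Chains are seeded from independent `SeedSequence` streams spawned off the
  user seed; identical seed + versions ⇒ byte-identical draws.

## Problem sizes used by the packaged checks

Recovery and acceptance runs use the 122-patient default cohort with
2 chains × (1000 + 1000) draws; the interval-coverage study uses 20
replicate cohorts of 30 patients × 10 draws with 2 chains × (300 + 300);
generator descriptors are measured at 4000 patients where the sample median
and mean are precise to a few percent. These sizes are the package's own
validation choices and scale linearly if enlarged.

## Known limitations

* The lifespan of RBCs created *during* treatment is not identifiable from
  this design (all new cells share one size distribution; their replacement
  is invisible to the MCV signal).
* The population is pooled across the three drugs; no drug covariate.
* The survival family is fixed LogNormal; no model comparison across
  families is implemented.
* With heavy eligibility filtering the retained cohort is a non-random
  subset of the generated one; the small induced bias on upper-tail MCV
  parameters (<0.2 fL under defaults) is ignored.
* R̂/ESS gates at the reduced draw budget are conservative; production
  analyses should use the 4-chain default configuration.
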