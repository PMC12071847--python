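# rbclifespan

Bayesian estimation of red-blood-cell (RBC) lifespan from routine
longitudinal complete blood counts (CBCs) in patients starting CDK4/6
inhibitors (palbociclib, ribociclib, abemaciclib).

## The problem

CDK4/6 inhibitors make newly produced RBCs larger (macrocytosis). Whether
they also *shorten the lifespan* of the RBCs that existed before treatment —
i.e. cause occult hemolysis — cannot be read off a hemoglobin value, because
compensated hemolysis leaves hemoglobin normal. Direct lifespan measurement
(cobalt/biotin labeling, CO rebreathing) is invasive and rarely available.

This package implements an indirect, model-based estimate. RBC volume is
essentially fixed after maturation, so cells made **before** treatment
("old", small, low MCV) are progressively replaced by cells made **under**
treatment ("new", large, high MCV). The speed at which the patient's mean
corpuscular volume (MCV) drifts upward is therefore governed by how fast old
cells die: fast MCV rise ⇒ short old-cell lifespan; slow rise ⇒ long one.

## The model

For patient *i* at time *t* (days since first dose; *t* < 0 before
treatment), with Φ the standard normal CDF:

    S(t)        = 1 − Φ((log t − μ_s) / σ_s)          LogNormal residual survival
    w_old(t)    = 1 for t ≤ 0,  S(t) for t > 0        fraction of old RBCs
    X_i,old     ~ Normal(μ_X,old,  σ_X,old)           X ∈ {N_RBC, MCV, MCHC}
    X_i,new     ~ Normal(μ_X,new,  σ_X,new)
    X_i(t)      ~ StudentT(ν_X, w_old(t)·X_i,old + (1−w_old(t))·X_i,new, σ_X)

Every observed index is a mixture mean of old/new patient-level values
weighted by the surviving old fraction, measured with heavy-tailed Student-T
noise (routine laboratory values are noisier than a Normal allows). The
quantity of interest is the **mean lifespan of pre-treatment RBCs**,
`exp(μ_s + σ_s²/2)`; the healthy-adult reference is ≈118 days. Hemoglobin is
reported through the identity `Hgb = N_RBC·MCV·MCHC/1000`.

The posterior is sampled with the No-U-Turn Hamiltonian Monte Carlo sampler
implemented in `rbclifespan.nuts` (analytic gradients, non-centered
hierarchy, dual-averaging step size, diagonal metric adaptation), and
criticized with rank plots, posterior predictive checks and PSIS-LOO
(`rbclifespan.diagnostics`, via arviz).

Because the clinical dataset that motivated the model is not public, the
package ships a calibrated synthetic-cohort generator
(`rbclifespan.synthetic_cohort`) that emulates the study conditions — 122
patients, baseline + biweekly(2 months) + monthly CBC schedule, LogNormal
treatment durations (median 7.2 months, IQR ≈ 3.4–13.3), pre/post MCV
87.8/100.2 fL — so the whole pipeline is validated by parameter recovery.

## Worked example

```bash
rbclifespan all --out run1 --seed 5 --chains 2 --warmup 400 --draws 400
```

simulates the default cohort, applies the eligibility rules (≥5 CBCs,
baseline MCV ≤ 98 fL, records within −28 days … end of continuous
treatment), fits the model and prints a report like:

```
Cohort (recomputed from filtered data)
  patients included: 106 (excluded: 16)
  CBC draws: 1549 (mean 14.6/patient)
  median continuous duration: 7.4 months

Posterior summaries (median [95% CdI])
               mcv_pre:    87.99  [87.14, 89.01]
              mcv_post:    99.93  [99.01, 101.16]
             mcv_delta:    11.91  [10.47, 13.40]
    rbc_delta_decrease:     0.74  [0.63, 0.92]
         lifespan_days:   116.70  [114.75, 118.75]
  ...
Recovery (generating truth vs posterior)
         lifespan_days: truth   118.00 vs   116.70 [114.75, 118.75] (inside 95% CdI)
```

(a different seed changes the simulated cohort and hence the decimals; a
short 400-draw run trades R-hat/ESS headroom for speed — use the 4-chain
2000+2000 default for production). The `mcv_pre`/`mcv_post` rows are
the population means of the pre- and post-treatment cell populations;
`lifespan_days` is the mean lifespan of pre-treatment RBCs in days — values
near 118 indicate no detectable drug-induced shortening.

The same stages are available programmatically:

```python
from rbclifespan import CohortConfig, FitConfig, generate_cohort, build_model, fit, summarize
from rbclifespan.cohort_io import apply_eligibility
from rbclifespan.pipeline import timelines_from_records

cohort = generate_cohort(CohortConfig(seed=1))
included, excluded = apply_eligibility(timelines_from_records(cohort.records))
result = fit(build_model(included), FitConfig(n_chains=2, n_warmup=1000, n_sampling=1000, seed=2))
print(summarize(result))
```

Real data enter through `read_cbc_table` (tidy CSV with columns
`patient_id, t_days | date+first_dose_date, rbc_1e12_per_L, mcv_fL,
mchc_g_dL`, optional dispensing CSV for continuous-treatment episodes).

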