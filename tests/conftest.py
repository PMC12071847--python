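"""Shared fixtures.

Heavy posterior fits are session-scoped so the structural, diagnostic and
acceptance tests share one sampling run each:

* ``small_fit`` — 20-patient cohort, quick 2x(400+400) fit.
* ``calibrated_fit`` — the full 122-patient default-calibration cohort with
  the reduced 2x(1000+1000) sampling configuration (the parameter-recovery
  reference run).
"""

from __future__ import annotations

import numpy as np
import pytest

from rbclifespan import (CohortConfig, FitConfig, PopulationParams, build_model,
                         fit, generate_cohort)
from rbclifespan.cohort_io import apply_eligibility
from rbclifespan.pipeline import timelines_from_records


def zero_noise_population(**overrides) -> PopulationParams:
    """Degenerate population: no hierarchy spread, no measurement noise."""
    kw = {f"sigma_{s}_{st}": 0.0 for s in ("n", "mcv", "mchc") for st in ("old", "new")}
    kw.update({"sigma_obs_n": 0.0, "sigma_obs_mcv": 0.0, "sigma_obs_mchc": 0.0})
    kw.update(overrides)
    return PopulationParams(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=20, seed=7))


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    model = build_model(small_cohort.records)
    return fit(model, FitConfig(n_chains=2, n_warmup=400, n_sampling=400, seed=11))


@pytest.fixture(scope="session")
def calibrated_cohort():
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def calibrated_eligible(calibrated_cohort):
    included, exclusions = apply_eligibility(
        timelines_from_records(calibrated_cohort.records))
    return included, exclusions


@pytest.fixture(scope="session")
def calibrated_fit(calibrated_eligible):
    included, _ = calibrated_eligible
    model = build_model(included)
    return fit(model, FitConfig(n_chains=2, n_warmup=1000, n_sampling=1000, seed=7))


@pytest.fixture(scope="session")
def calibrated_truth(calibrated_cohort, calibrated_eligible):
    """Realized (sample-mean) true values of the included patients.

    A single finite cohort's identifiable targets are its realized means;
    the population-level claim is covered by the multi-replicate coverage
    study.
    """
    included, _ = calibrated_eligible
    ids = [tl.patient_id for tl in included]
    m = calibrated_cohort.truth.set_index("patient_id").loc[ids].mean()
    out = {
        "mcv_pre": m["mcv_old"], "mcv_post": m["mcv_new"],
        "mcv_delta": m["mcv_new"] - m["mcv_old"],
        "mchc_delta": m["mchc_new"] - m["mchc_old"],
        "rbc_delta_decrease": m["n_old"] - m["n_new"],
        "hgb_delta": (m["n_new"] * m["mcv_new"] * m["mchc_new"]
                      - m["n_old"] * m["mcv_old"] * m["mchc_old"]) / 1000.0,
    }
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
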