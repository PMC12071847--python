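"""Generator behavior: schedules, reproducibility, noise-free collapse,
law-of-large-numbers calibration."""

import numpy as np
import pandas as pd
import pytest

from rbclifespan.core_model import SurvivalParams, mixture_mean, old_fraction
from rbclifespan.synthetic_cohort import (DAYS_PER_MONTH, CohortConfig,
                                          PopulationParams,
                                          draw_patient_params,
                                          duration_lognormal_params,
                                          generate_cohort, read_cohort_csv,
                                          sampling_schedule,
                                          simulate_observation, write_cohort)
from conftest import zero_noise_population


class _FixedBaselineRng:
    """Stand-in rng whose uniform() returns a fixed baseline day."""

    def __init__(self, baseline):
        self.baseline = baseline

    def uniform(self, lo, hi):
        return self.baseline


class TestSamplingSchedule:
    def test_biweekly_then_monthly(self):
        times = sampling_schedule(180.0, 28.0, _FixedBaselineRng(-14.0))
        assert times.tolist() == [-14.0, 14.0, 28.0, 42.0, 56.0, 84.0, 112.0, 140.0, 168.0]

    def test_stops_at_duration(self):
        times = sampling_schedule(60.0, 28.0, _FixedBaselineRng(-7.0))
        assert times.tolist() == [-7.0, 14.0, 28.0, 42.0, 56.0]

    def test_short_duration_gives_baseline_only(self):
        times = sampling_schedule(10.0, 28.0, np.random.default_rng(0))
        assert len(times) == 1 and -28.0 <= times[0] < 0.0

    def test_strictly_increasing_and_bounded(self, rng):
        for duration in (15.0, 57.0, 100.0, 400.0, 1000.0):
            times = sampling_schedule(duration, 28.0, rng)
            assert np.all(np.diff(times) > 0)
            assert times[0] < 0 <= times[1] if len(times) > 1 else True
            assert times.max() <= duration

    def test_nonpositive_duration_rejected(self, rng):
        with pytest.raises(ValueError):
            sampling_schedule(0.0, 28.0, rng)


class TestPatientParams:
    def test_degenerate_hierarchy_returns_means(self):
        pop = zero_noise_population()
        p = draw_patient_params(pop, np.random.default_rng(1))
        assert p.mcv_old == pop.mu_mcv_old and p.mcv_new == pop.mu_mcv_new
        assert p.n_old == pop.mu_n_old and p.mchc_new == pop.mu_mchc_new

    def test_law_of_large_numbers_calibration(self):
        pop = PopulationParams()
        prng = np.random.default_rng(3)
        draws = np.array([draw_patient_params(pop, prng).mcv_old for _ in range(10_000)])
        se = pop.sigma_mcv_old / np.sqrt(draws.size)
        assert abs(draws.mean() - 87.8) < 3 * se

    def test_same_seed_same_stream(self):
        a = [draw_patient_params(PopulationParams(), np.random.default_rng(9)) for _ in range(3)]
        b = [draw_patient_params(PopulationParams(), np.random.default_rng(9)) for _ in range(3)]
        assert a == b

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams(sigma_mcv_old=-1.0)
        with pytest.raises(ValueError):
            PopulationParams(nu_mcv=1.0)


class TestSimulateObservation:
    def test_noise_free_pretreatment_equals_old_values(self, rng):
        pop = zero_noise_population()
        patient = draw_patient_params(pop, rng)
        survival = SurvivalParams.from_mean_lifespan(118.0, 0.3)
        rec = simulate_observation(-10.0, patient, pop, survival, rng)
        assert rec["mcv_fL"] == patient.mcv_old
        assert rec["rbc_1e12_per_L"] == patient.n_old
        assert rec["mchc_g_dL"] == patient.mchc_old

    def test_noise_free_full_replacement_equals_new_values(self, rng):
        pop = zero_noise_population()
        patient = draw_patient_params(pop, rng)
        survival = SurvivalParams.from_mean_lifespan(118.0, 0.3)
        rec = simulate_observation(1e7, patient, pop, survival, rng)
        assert rec["mcv_fL"] == pytest.approx(patient.mcv_new, abs=1e-9)

    def test_noise_free_midpoint_at_survival_median(self, rng):
        pop = zero_noise_population()
        patient = draw_patient_params(pop, rng)
        survival = SurvivalParams.from_mean_lifespan(118.0, 0.3)
        rec = simulate_observation(np.exp(survival.mu_survival), patient, pop, survival, rng)
        assert rec["mcv_fL"] == pytest.approx((patient.mcv_old + patient.mcv_new) / 2)


class TestGenerateCohort:
    def test_default_cohort_shape(self, calibrated_cohort):
        records = calibrated_cohort.records
        assert records["patient_id"].nunique() == 122
        # gross sanity only: the 122-patient sample mean is noisy (heavy-tailed
        # durations); the precise calibration check runs at large n elsewhere
        draws_per_patient = records.groupby("patient_id").size()
        assert 8.0 < draws_per_patient.mean() < 25.0
        assert (records[["rbc_1e12_per_L", "mcv_fL", "mchc_g_dL"]] > 0).all().all()

    def test_duration_law_matches_reference_quantiles(self):
        mu, sd = duration_lognormal_params()
        assert np.exp(mu) == pytest.approx(7.2)
        # IQR reproduced approximately (law is over-determined by 3 quantiles)
        q1, q3 = np.exp(mu - 0.6745 * sd), np.exp(mu + 0.6745 * sd)
        assert q1 == pytest.approx(3.4, rel=0.12)
        assert q3 == pytest.approx(13.3, rel=0.12)

    def test_median_duration_near_reference(self, calibrated_cohort):
        med = calibrated_cohort.truth["duration_days"].median() / DAYS_PER_MONTH
        assert 5.0 < med < 10.0  # n=122 sample median of the 7.2-month law

    def test_same_seed_identical_tables(self):
        cfg = CohortConfig(n_patients=12, seed=99)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_noise_free_records_lie_on_mixture_curve(self):
        cfg = CohortConfig(n_patients=6, seed=4, population=zero_noise_population())
        coh = generate_cohort(cfg)
        pop, surv = cfg.population, cfg.survival
        w = old_fraction(coh.records["t_days"].to_numpy(), surv)
        expected = mixture_mean(w, pop.mu_mcv_old, pop.mu_mcv_new)
        np.testing.assert_allclose(coh.records["mcv_fL"], expected, atol=1e-9)

    def test_empirical_mean_converges_to_mixture_curve(self):
        # per-time-point mean MCV over many patients follows the population curve
        cfg = CohortConfig(n_patients=10_000, seed=12, max_followup=170.0,
                           duration_log_sd=0.0, duration_log_median=np.log(160 / DAYS_PER_MONTH))
        coh = generate_cohort(cfg)
        pop = cfg.population
        on_drug = coh.records[coh.records["t_days"] > 0]
        for t, grp in on_drug.groupby("t_days"):
            w = old_fraction(t, cfg.survival)
            expected = mixture_mean(w, pop.mu_mcv_old, pop.mu_mcv_new)
            spread = np.sqrt(w**2 * pop.sigma_mcv_old**2 + (1 - w)**2 * pop.sigma_mcv_new**2
                             + pop.nu_mcv / (pop.nu_mcv - 2) * pop.sigma_obs_mcv**2)
            se = spread / np.sqrt(len(grp))
            assert abs(grp["mcv_fL"].mean() - expected) < 3.5 * se

    def test_truth_table_has_one_row_per_patient(self, calibrated_cohort):
        assert len(calibrated_cohort.truth) == 122
        assert calibrated_cohort.truth["patient_id"].is_unique


def test_cohort_csv_roundtrip(tmp_path):
    coh = generate_cohort(CohortConfig(n_patients=5, seed=8))
    rec_path, truth_path = tmp_path / "rec.csv", tmp_path / "truth.csv"
    write_cohort(coh, rec_path, truth_path)
    assert rec_path.read_text().startswith("# seed = 8\n")
    back = read_cohort_csv(rec_path)
    pd.testing.assert_frame_equal(back, coh.records, check_exact=False, rtol=1e-12)


def test_config_yaml_roundtrip():
    cfg = CohortConfig(n_patients=9, seed=5)
    back = CohortConfig.from_yaml(cfg.to_yaml())
    assert back == cfg
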