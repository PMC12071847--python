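"""Ingestion, time alignment, continuous-treatment episodes, eligibility."""

import numpy as np
import pandas as pd
import pytest

from rbclifespan.cohort_io import (EligibilityRules, PatientTimeline,
                                   apply_eligibility, continuous_duration,
                                   read_cbc_table)
from rbclifespan.synthetic_cohort import CohortConfig, generate_cohort, write_cohort


def _timeline(pid, t, mcv=90.0, dispensing=None):
    t = np.asarray(t, dtype=float)
    mcv = np.broadcast_to(np.asarray(mcv, dtype=float), t.shape)
    df = pd.DataFrame({
        "patient_id": pid, "t_days": t,
        "rbc_1e12_per_L": 4.5, "mcv_fL": mcv, "mchc_g_dL": 33.0,
    })
    return PatientTimeline(pid, df, dispensing)


class TestReadCbcTable:
    def test_roundtrips_generated_cohort(self, tmp_path):
        coh = generate_cohort(CohortConfig(n_patients=4, seed=2))
        path = tmp_path / "cohort.csv"
        write_cohort(coh, path)
        timelines = read_cbc_table(path)
        assert len(timelines) == 4
        stacked = pd.concat([tl.records for tl in timelines], ignore_index=True)
        assert len(stacked) == len(coh.records)
        np.testing.assert_allclose(
            np.sort(stacked["mcv_fL"]), np.sort(coh.records["mcv_fL"]))

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,t_days,rbc_1e12_per_L,mchc_g_dL\nA,0,4.5,33\n")
        with pytest.raises(ValueError, match="mcv_fL"):
            read_cbc_table(path)

    def test_unparseable_number_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,t_days,rbc_1e12_per_L,mcv_fL,mchc_g_dL\n"
                        "A,0,4.5,90,33\nA,14,4.5,oops,33\n")
        with pytest.raises(ValueError, match="mcv_fL"):
            read_cbc_table(path)

    def test_duplicates_keep_first(self, tmp_path, caplog):
        path = tmp_path / "dup.csv"
        path.write_text("patient_id,t_days,rbc_1e12_per_L,mcv_fL,mchc_g_dL\n"
                        "A,0,4.5,90,33\nA,0,4.5,95,33\nA,14,4.5,91,33\n")
        with caplog.at_level("INFO", logger="rbclifespan.cohort_io"):
            timelines = read_cbc_table(path)
        assert len(timelines[0].records) == 2
        assert timelines[0].records["mcv_fL"].iloc[0] == 90.0
        assert any("duplicate" in r.message for r in caplog.records)

    def test_calendar_dates_become_day_offsets(self, tmp_path):
        path = tmp_path / "dates.csv"
        path.write_text(
            "patient_id,date,first_dose_date,rbc_1e12_per_L,mcv_fL,mchc_g_dL\n"
            "A,2020-01-01,2020-01-15,4.5,90,33\n"
            "A,2020-02-12,2020-01-15,4.4,92,33\n")
        (tl,) = read_cbc_table(path)
        assert tl.records["t_days"].tolist() == [-14.0, 28.0]

    def test_day_offsets_invariant_to_global_calendar_shift(self, tmp_path):
        # only offsets from the first dose matter, not absolute dates
        rows = [("2021-03-01", "2021-03-10"), ("2021-04-07", "2021-03-10")]
        shifted = [("2023-03-01", "2023-03-10"), ("2023-04-07", "2023-03-10")]
        out = []
        for i, rs in enumerate((rows, shifted)):
            path = tmp_path / f"shift{i}.csv"
            body = "".join(f"A,{d},{fd},4.5,90,33\n" for d, fd in rs)
            path.write_text(
                "patient_id,date,first_dose_date,rbc_1e12_per_L,mcv_fL,mchc_g_dL\n" + body)
            (tl,) = read_cbc_table(path)
            out.append(tl.records["t_days"].tolist())
        assert out[0] == out[1]

    def test_schema_config_renames_columns(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text("id,day,RBC,MCV,MCHC\nA,0,4.5,90,33\nA,14,4.4,91,33\n")
        timelines = read_cbc_table(path, schema_config={
            "id": "patient_id", "day": "t_days", "RBC": "rbc_1e12_per_L",
            "MCV": "mcv_fL", "MCHC": "mchc_g_dL"})
        assert len(timelines[0].records) == 2


class TestContinuousDuration:
    def test_uninterrupted_episode_ends_one_cycle_after_last_dispensing(self):
        tl = _timeline("A", [0, 30], dispensing=[0, 28, 56])
        assert continuous_duration(tl) == 56 + 28

    def test_gap_breaks_episode(self):
        tl = _timeline("A", [0, 30], dispensing=[0, 28, 70])
        assert continuous_duration(tl) == 28 + 28  # 42-day gap >= 30 breaks

    def test_single_dispensing_is_one_cycle(self):
        tl = _timeline("A", [0], dispensing=[0])
        assert continuous_duration(tl) == 28

    def test_no_dispensing_falls_back_to_last_record(self, caplog):
        tl = _timeline("A", [-7, 14, 100])
        with caplog.at_level("INFO", logger="rbclifespan.cohort_io"):
            assert continuous_duration(tl) == 100
        assert any("no dispensing info" in r.message for r in caplog.records)


class TestApplyEligibility:
    def test_too_few_cbcs_excluded(self):
        ok = _timeline("A", [-7, 14, 28, 42, 56])
        short = _timeline("B", [-7, 14, 28, 42])
        included, log = apply_eligibility([ok, short])
        assert [tl.patient_id for tl in included] == ["A"]
        assert log.set_index("patient_id").loc["B", "reason"] == "insufficient_cbc_count"

    @pytest.mark.parametrize("baseline_mcv,included_expected", [(98.0, True), (99.0, False)])
    def test_baseline_macrocytosis_boundary(self, baseline_mcv, included_expected):
        mcv = [baseline_mcv, 90, 90, 90, 90]
        tl = _timeline("A", [-7, 14, 28, 42, 56], mcv=mcv)
        included, log = apply_eligibility([tl])
        assert bool(included) is included_expected
        if not included_expected:
            assert log["reason"].iloc[0] == "baseline_macrocytosis"

    def test_baseline_is_latest_pretreatment_draw(self):
        # the -3d draw (99 fL) is the baseline, not the -20d one (90 fL)
        tl = _timeline("A", [-20, -3, 14, 28, 42, 56], mcv=[90, 99, 90, 90, 90, 90])
        included, log = apply_eligibility([tl])
        assert not included and log["reason"].iloc[0] == "baseline_macrocytosis"

    def test_missing_baseline_uses_early_ontreatment_draw(self):
        tl = _timeline("A", [10, 28, 42, 56, 84], mcv=[99, 90, 90, 90, 90])
        included, log = apply_eligibility([tl])
        assert not included and log["reason"].iloc[0] == "baseline_macrocytosis"

    def test_no_usable_baseline_flagged(self):
        tl = _timeline("A", [30, 56, 84, 112, 140])
        included, log = apply_eligibility([tl])
        assert not included and log["reason"].iloc[0] == "no_baseline"

    def test_records_trimmed_to_analysis_window(self):
        tl = _timeline("A", [-40, -7, 14, 28, 42, 56, 200], dispensing=[0, 28, 56])
        included, _ = apply_eligibility([tl])
        t = included[0].records["t_days"]
        assert t.min() >= -28 and t.max() <= 56 + 28

    def test_idempotent(self):
        tls = [_timeline("A", [-7, 14, 28, 42, 56]),
               _timeline("B", [-7, 14, 28, 42]),
               _timeline("C", [-7, 14, 28, 42, 56], mcv=[99, 90, 90, 90, 90])]
        once, log1 = apply_eligibility(tls)
        twice, log2 = apply_eligibility(once)
        assert [t.patient_id for t in twice] == [t.patient_id for t in once]
        assert len(log2) == 0

    def test_partition_and_single_reason(self, calibrated_cohort):
        from rbclifespan.pipeline import timelines_from_records
        tls = timelines_from_records(calibrated_cohort.records)
        included, log = apply_eligibility(tls)
        assert len(included) + len(log) == len(tls)
        assert log["patient_id"].is_unique
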