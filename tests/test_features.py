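"""Predictor builders: dose arithmetic, overlap chains, matrix contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opiphen import (EligibilityConfig, PredictorSpec, build_cohort,
                     build_matrix, build_predictor, daily_meq_series,
                     default_spec_library, detect_overlap_events,
                     risk_ratio_screen)
from opiphen.synthetic import ClaimsDataset
from .conftest import make_dispensings, overlap_oracle

WINDOW = (pd.Timestamp("2010-01-01"), pd.Timestamp("2012-12-31"))


def _member(index="2011-01-01", age=45.0, sex="F"):
    idx = pd.Timestamp(index)
    return {"observation_start": idx - pd.DateOffset(months=12),
            "observation_end": idx + pd.DateOffset(months=24)
            - pd.Timedelta(days=1),
            "age_at_index": age, "sex": sex}


class TestDailyMeq:
    def test_single_fill_rate(self):
        # 30 units x 10 mg x factor 1.5 over 30 days -> 15 MEQ/day
        disp = make_dispensings([("2010-02-01", "ERLA_opioid", 30, 30.0, 10.0,
                                  1.5)])
        s = daily_meq_series(disp, (pd.Timestamp("2010-01-01"),
                                    pd.Timestamp("2010-12-31")))
        jan31 = 31
        assert np.allclose(s[jan31:jan31 + 30], 15.0)
        assert s[:jan31].sum() == 0 and s[jan31 + 30:].sum() == 0

    def test_overlapping_fills_add(self):
        rows = [("2010-02-01", "ERLA_opioid", 30, 30.0, 10.0, 1.5)] * 2
        s = daily_meq_series(make_dispensings(rows),
                             (pd.Timestamp("2010-02-01"),
                              pd.Timestamp("2010-03-10")))
        assert np.allclose(s[:30], 30.0)

    def test_no_opioids_all_zero(self):
        disp = make_dispensings([("2010-02-01", "benzodiazepine", 30)])
        s = daily_meq_series(disp, WINDOW)
        assert (s == 0).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 90),
                              st.floats(1, 200), st.floats(0.1, 3)),
                    max_size=8))
    def test_mass_conservation(self, fills):
        """The series integrates to the total dispensed morphine equivalents
        when every fill's coverage lies inside the window."""
        rows = [(pd.Timestamp("2010-01-01") + pd.Timedelta(days=d),
                 "IR_opioid", s, q, 10.0, m) for d, s, q, m in fills]
        disp = make_dispensings(rows)
        series = daily_meq_series(disp, (pd.Timestamp("2010-01-01"),
                                         pd.Timestamp("2013-12-31")))
        expected = sum(q * 10.0 * m for _, s, q, m in fills)
        assert series.sum() == pytest.approx(expected, rel=1e-9)


class TestOverlapEvents:
    def test_weekend_chain_of_three(self):
        # Sat Jan-02 (10 d), Mon Jan-04 (7 d), Sun Jan-10 (14 d), all <= 14 d
        fills = make_dispensings([("2010-01-02", "IR_opioid", 10),
                                  ("2010-01-04", "IR_opioid", 7),
                                  ("2010-01-10", "IR_opioid", 14)])
        assert detect_overlap_events(fills) is True

    def test_midweek_fill_breaks_the_day_filter(self):
        # the middle fill moves to Wednesday Jan-06: only two qualify
        fills = make_dispensings([("2010-01-02", "IR_opioid", 10),
                                  ("2010-01-06", "IR_opioid", 7),
                                  ("2010-01-10", "IR_opioid", 14)])
        assert detect_overlap_events(fills) is False

    def test_on_schedule_refills_never_overlap(self):
        rows = [(pd.Timestamp("2010-01-02") + pd.Timedelta(days=30 * k),
                 "IR_opioid", 14) for k in range(6)]
        assert detect_overlap_events(make_dispensings(rows),
                                     dow_set=None) is False

    def test_agrees_with_coverage_day_set_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(250):
            n = rng.integers(0, 9)
            rows = [(pd.Timestamp("2010-01-01") +
                     pd.Timedelta(days=int(rng.integers(0, 200))),
                     "IR_opioid" if rng.random() < 0.8 else "ERLA_opioid",
                     int(rng.choice([3, 7, 10, 14, 21, 30])))
                    for _ in range(n)]
            fills = make_dispensings(rows)
            kw = dict(class_filter=("IR_opioid",), max_days_supply=14,
                      dow_set=("Sat", "Sun", "Mon"), window_len_months=3)
            assert detect_overlap_events(fills, **kw) == \
                overlap_oracle(fills, **kw)


class TestBuilders:
    def test_diagnosis_flag(self):
        dx = pd.DataFrame([("P1", pd.Timestamp("2010-08-01"), "304.01",
                            "outpatient")],
                          columns=["patient_id", "date", "code", "setting"])
        spec = PredictorSpec("f", "diagnosis_flag",
                             {"code_group": "opioid_dependence"})
        assert build_predictor({"diagnoses": dx}, spec, _member()) == 1.0
        out_of_window = dx.assign(date=pd.Timestamp("2014-01-01"))
        assert build_predictor({"diagnoses": out_of_window}, spec,
                               _member()) == 0.0

    def test_pct_quarters(self):
        # window 2010-01-01..2012-12-31 has exactly 12 calendar quarters
        dates = ["2010-02-10", "2011-05-10", "2012-11-10"]
        dx = pd.DataFrame([("P1", pd.Timestamp(d), "724.2", "outpatient")
                           for d in dates],
                          columns=["patient_id", "date", "code", "setting"])
        spec = PredictorSpec("p", "pct_quarters", {"code_group": "back_pain"},
                             "proportion")
        assert build_predictor({"diagnoses": dx}, spec,
                               _member("2011-01-01")) == pytest.approx(3 / 12)

    def test_interaction_indicator_product(self):
        fills = make_dispensings([("2010-06-05", "IR_opioid", 10),
                                  ("2010-06-07", "IR_opioid", 7),
                                  ("2010-06-13", "IR_opioid", 14)])
        specs = [
            PredictorSpec("age_18_34", "demographic", {"field": "age_18_34"}),
            PredictorSpec("overlap", "overlap_fills",
                          {"drug_classes": ("IR_opioid",), "max_days_supply": 14,
                           "dow_set": ("Sat", "Sun", "Mon")}),
            PredictorSpec("ix", "interaction",
                          {"left": "age_18_34", "right": "overlap"},
                          "continuous"),
        ]
        ds = _dataset_for(fills)
        cohort = _cohort_row(age=50.0)
        m = build_matrix(ds, cohort, specs)
        assert m.values.loc["P1", "overlap"] == 1.0
        assert m.values.loc["P1", "ix"] == 0.0  # 50-year-old: indicator is 0
        m_young = build_matrix(ds, _cohort_row(age=25.0), specs)
        assert m_young.values.loc["P1", "ix"] == 1.0


def _dataset_for(disp, dx=None):
    demo = pd.DataFrame([("P1", pd.Timestamp("1965-01-01"), "F", "White",
                          False)],
                        columns=["patient_id", "birth_date", "sex", "race",
                                 "excluded_care"])
    empty_dx = pd.DataFrame(columns=["patient_id", "date", "code", "setting"])
    return ClaimsDataset(
        demo, pd.DataFrame(columns=["patient_id", "start_date", "end_date"]),
        disp, dx if dx is not None else empty_dx,
        pd.DataFrame(columns=["patient_id", "date", "setting"]),
        pd.DataFrame(columns=["patient_id", "date", "category"]),
        pd.DataFrame([("P1", False, pd.NaT)],
                     columns=["patient_id", "problem_use", "onset_date"]))


def _cohort_row(age=45.0, index="2010-06-01"):
    m = _member(index, age)
    return pd.DataFrame([{"patient_id": "P1", "index_date": pd.Timestamp(index),
                          "observation_start": m["observation_start"],
                          "observation_end": m["observation_end"],
                          "outcome_36m": False, "age_at_index": age}])


class TestMatrix:
    def test_empty_cohort_keeps_full_header(self):
        ds = _dataset_for(make_dispensings([]))
        m = build_matrix(ds, _cohort_row().iloc[0:0])
        assert m.values.shape == (0, len(default_spec_library()))

    def test_patient_with_no_events_gets_zero_row_plus_demographics(self):
        ds = _dataset_for(make_dispensings([]))
        m = build_matrix(ds, _cohort_row(age=30.0))
        row = m.values.loc["P1"]
        demo_cols = {"age_at_index", "age_18_34", "age_35_54", "age_55_64",
                     "age_65_plus", "sex_female"}
        assert (row.drop(labels=demo_cols) == 0).all()
        assert row["age_at_index"] == 30.0
        assert row["age_18_34"] == 1.0 and row["sex_female"] == 1.0

    def test_matrix_has_no_missing_cells_and_binary_columns_are_binary(
            self, small_dataset, small_cohort):
        m = build_matrix(small_dataset, small_cohort.head(40))
        assert not m.values.isna().any().any()
        for name, spec in m.specs.items():
            if spec.output_type == "binary":
                assert set(np.unique(m.values[name])) <= {0.0, 1.0}, name

    def test_matrix_invariant_to_record_order(self, small_dataset,
                                              small_cohort):
        cohort = small_cohort.head(25)
        base = build_matrix(small_dataset, cohort)
        shuffled = ClaimsDataset(
            small_dataset.demographics,
            small_dataset.enrollment,
            small_dataset.dispensings.sample(frac=1, random_state=8),
            small_dataset.diagnoses.sample(frac=1, random_state=9),
            small_dataset.encounters.sample(frac=1, random_state=10),
            small_dataset.procedures.sample(frac=1, random_state=11),
            small_dataset.labels,
            study_start=small_dataset.study_start,
            study_end=small_dataset.study_end)
        other = build_matrix(shuffled, cohort)
        pd.testing.assert_frame_equal(base.values, other.values)

    def test_duplicate_spec_names_rejected(self, small_dataset, small_cohort):
        from opiphen import ConfigError
        specs = [PredictorSpec("same", "charlson", {}),
                 PredictorSpec("same", "charlson", {})]
        with pytest.raises(ConfigError, match="same"):
            build_matrix(small_dataset, small_cohort.head(2), specs)

    def test_catalog_covers_every_builder_family(self):
        from opiphen.features import FAMILIES
        families = {s.family for s in default_spec_library()}
        assert families == set(FAMILIES)


class TestRRScreen:
    def test_rr_arithmetic(self):
        y = np.r_[np.ones(200, bool), np.zeros(800, bool)]
        flag = np.r_[np.ones(80), np.zeros(120), np.ones(80), np.zeros(720)]
        df = pd.DataFrame({"p": flag})
        out = risk_ratio_screen(df, y).iloc[0]
        assert out["rr"] == pytest.approx(4.0)
        assert out["n_true"] == 160
        assert not out["undefined"]

    def test_always_true_predictor_has_rr_one(self):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        out = risk_ratio_screen(pd.DataFrame({"p": np.ones(20)}), y).iloc[0]
        assert out["rr"] == pytest.approx(1.0)

    def test_zero_denominator_marks_undefined_not_infinite(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        flag = np.r_[np.ones(3), np.zeros(7)]
        out = risk_ratio_screen(pd.DataFrame({"p": flag}), y).iloc[0]
        assert out["undefined"]
        assert np.isnan(out["rr"])

    def test_elevated_streams_screen_above_one(self, small_dataset,
                                               small_cohort):
        m = build_matrix(small_dataset, small_cohort)
        y = small_cohort["outcome_36m"].to_numpy(dtype=bool)
        scr = risk_ratio_screen(m, y).set_index("predictor")
        for name in ("overlap_ir14_3in3mo", "rx_oud_treatment_ever",
                     "er_during_opioid_ever"):
            row = scr.loc[name]
            assert row["undefined"] or row["rr"] > 1.0, name
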