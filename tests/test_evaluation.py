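"""Confusion metrics, ROC, cut-point schemes, comparator, and CI helper."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from opiphen import (ConfusionMetrics, CutpointError, CutpointScheme,
                     DataError, binomial_ci, confusion_metrics,
                     icd9_classifier, roc_auc, roc_points, select_cutpoint,
                     table3_report)
from opiphen.evaluation import DEFAULT_SCHEMES
from .conftest import cutpoint_oracle


def _scores_outcomes(tp=90, fn=10, fp=60, tn=840):
    scores = np.r_[np.ones(tp + fp), np.zeros(fn + tn)]
    y = np.r_[np.ones(tp, bool), np.zeros(fp, bool),
              np.ones(fn, bool), np.zeros(tn, bool)]
    return scores, y


class TestConfusion:
    def test_worked_example(self):
        scores, y = _scores_outcomes()
        m = confusion_metrics(scores, y, cut=0.5)
        assert m == ConfusionMetrics(tp=90, fp=60, tn=840, fn=10)
        assert m.sensitivity == pytest.approx(0.900)
        assert m.specificity == pytest.approx(0.933, abs=5e-4)
        assert m.ppv == pytest.approx(0.600)
        assert m.npv == pytest.approx(0.988, abs=5e-4)
        assert m.predicted_prevalence == pytest.approx(0.15)

    def test_classify_all_positive_limit(self):
        s = np.array([0.2, 0.5, 0.9])
        y = np.array([True, False, True])
        m = confusion_metrics(s, y, cut=0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.predicted_prevalence == 1.0
        assert m.npv is None  # no negatives classified

    def test_classify_all_negative_limit(self):
        s = np.array([0.2, 0.5, 0.9])
        y = np.array([True, False, True])
        m = confusion_metrics(s, y, cut=1.1)
        assert m.ppv is None  # undefined, not 0
        assert m.npv == pytest.approx(1 / 3)

    def test_metric_identities_on_integer_counts(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        y = rng.random(200) < 0.4
        m = confusion_metrics(s, y, cut=0.5)
        assert m.ppv * (m.tp + m.fp) == pytest.approx(m.tp)
        assert m.sensitivity + m.fn / (m.tp + m.fn) == pytest.approx(1.0)


class TestROC:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        s = rng.random(300)
        y = rng.random(300) < 0.3
        pts = roc_points(s, y)
        assert pts.iloc[0]["fpr"] == 0.0 and pts.iloc[0]["tpr"] == 0.0
        assert pts.iloc[-1]["fpr"] == 1.0 and pts.iloc[-1]["tpr"] == 1.0
        assert (np.diff(pts["fpr"]) >= 0).all()
        assert (np.diff(pts["tpr"]) >= 0).all()

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(2)
        y = rng.random(500) < 0.35
        s = np.round(rng.random(500) + 0.5 * y, 2)  # heavy ties
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_perfect_separation_passes_through_top_left(self):
        s = np.r_[np.full(5, 0.9), np.full(5, 0.1)]
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        pts = roc_points(s, y)
        assert ((pts["fpr"] == 0.0) & (pts["tpr"] == 1.0)).any()

    def test_sign_reversal_reflects_the_curve(self):
        rng = np.random.default_rng(3)
        y = rng.random(400) < 0.5
        s = rng.normal(size=400) + y
        assert roc_auc(-s, y) == pytest.approx(1.0 - roc_auc(s, y))

    def test_uninformative_scores_give_auc_half(self):
        rng = np.random.default_rng(4)
        y = rng.random(20_000) < 0.3
        s = rng.random(20_000)
        assert roc_auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            roc_points([0.1, 0.2], [True, True])


class TestCutpoints:
    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(60):
            n = int(rng.integers(8, 50))
            s = np.round(rng.random(n), 2)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            for scheme in DEFAULT_SCHEMES:
                expected = cutpoint_oracle(s, y, scheme.kind, scheme.target)
                if expected is None:
                    with pytest.raises(CutpointError):
                        select_cutpoint(s, y, scheme)
                else:
                    assert select_cutpoint(s, y, scheme) == expected, \
                        (trial, scheme.label)

    def test_full_sensitivity_cut_at_or_below_lowest_positive(self):
        s = np.array([0.9, 0.7, 0.3, 0.2, 0.1])
        y = np.array([True, False, True, False, False])
        cut = select_cutpoint(s, y, CutpointScheme("sensitivity", 1.0))
        assert cut <= 0.3

    def test_balanced_hits_exact_equality_when_available(self):
        # at cut 0.6: two positives classified, one false positive ->
        # sens 2/2=1? construct sens == ppv exactly at a cut
        s = np.array([0.9, 0.8, 0.6, 0.4, 0.2])
        y = np.array([True, False, True, True, False])
        # cut 0.6 -> TP=2, FP=1, FN=1: sens=2/3, ppv=2/3
        cut = select_cutpoint(s, y, CutpointScheme("balanced"))
        assert cut == pytest.approx(0.6)

    def test_unattainable_target_reports_best_attainable(self):
        s = np.array([0.9, 0.8, 0.6])
        y = np.array([False, True, False])
        with pytest.raises(CutpointError, match="best attainable"):
            select_cutpoint(s, y, CutpointScheme("ppv", 1.0))


class TestComparator:
    def _cohort(self):
        return pd.DataFrame([
            {"patient_id": "P1",
             "observation_start": pd.Timestamp("2009-06-01"),
             "observation_end": pd.Timestamp("2012-05-31")}])

    @pytest.mark.parametrize("code,date,expected", [
        ("304.01", "2010-01-15", True),
        ("304.01", "2012-06-01", False),   # one day after the window
        ("965.01", "2010-01-15", False),   # heroin-specific poisoning excluded
        ("965.00", "2009-06-01", True),    # first day of the window
        ("E850.2", "2011-12-31", True),
        ("724.2", "2010-01-15", False),
    ])
    def test_window_and_code_rules(self, code, date, expected):
        dx = pd.DataFrame([("P1", pd.Timestamp(date), code, "outpatient")],
                          columns=["patient_id", "date", "code", "setting"])
        got = icd9_classifier(dx, self._cohort())
        assert bool(got.loc["P1"]) is expected


class TestBinomialCI:
    def test_power_statement_specificity_interval(self):
        assert binomial_ci(0.80, 480, 0.95) == (76, 84)

    def test_degenerate_proportion_clips(self):
        assert binomial_ci(1.0, 10, 0.95) == (100, 100)

    def test_half_at_n_100(self):
        assert binomial_ci(0.5, 100, 0.95) == (40, 60)

    def test_exact_method_brackets_wald(self):
        lo_w, hi_w = binomial_ci(0.8, 480, 0.95, whole_percent=False)
        lo_e, hi_e = binomial_ci(0.8, 480, 0.95, method="exact",
                                 whole_percent=False)
        assert 70 < lo_e < 80 < hi_e < 90
        assert abs(lo_e - lo_w) < 1.5 and abs(hi_e - hi_w) < 1.5


class TestReport:
    def _data(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.35
        s = np.clip(rng.normal(0.35 + 0.4 * y, 0.18), 0, 1)
        return s, y

    def test_ten_schemes_plus_comparator(self):
        s_tr, y_tr = self._data(0)
        s_va, y_va = self._data(1, 150)
        comp_tr = (s_tr > 0.55).astype(float)
        comp_va = (s_va > 0.55).astype(float)
        rep = table3_report(s_tr, y_tr, s_va, y_va, comp_tr, comp_va)
        assert len(rep) == 11
        assert rep["scheme"].iloc[-1] == "icd9_comparator"

    def test_validation_metrics_use_training_cut(self):
        s_tr, y_tr = self._data(2)
        s_va, y_va = self._data(3, 150)
        rep = table3_report(s_tr, y_tr, s_va, y_va)
        row = rep[rep["scheme"] == "sensitivity@0.90"].iloc[0]
        m = confusion_metrics(s_va, y_va, row["cut"])
        assert row["valid_sensitivity"] == m.sensitivity
        assert row["train_sensitivity"] >= 0.90

    def test_empty_split_raises(self):
        s, y = self._data(4)
        with pytest.raises(DataError, match="validation"):
            table3_report(s, y, np.array([]), np.array([], dtype=bool))
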