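"""Splits, metrics and the robustness sweep."""

import numpy as np
import pandas as pd
import pytest

from ecgrobust.classify import ModelSpec, fit
from ecgrobust.containers import SegmentTable
from ecgrobust.errors import InvalidArgumentError, InvalidStateError
from ecgrobust.evaluate import (ConfusionMatrix, SplitSpec, inter_patient_split,
                                metrics_from_confusion, normalize_confusion,
                                robustness_sweep, round_half_up, split_patients)


def _table(patient_ids, labels, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(len(patient_ids), n_features))
    meta = pd.DataFrame({
        "patient_id": patient_ids,
        "lead_id": ["L0"] * len(patient_ids),
        "label": labels,
        "r_peak": np.zeros(len(patient_ids), dtype=int),
    })
    return SegmentTable(X, meta)


class TestInterPatientSplit:
    def test_group_sizes_and_lead_record_arithmetic(self):
        ids = {lab: [f"{lab}{i:03d}" for i in range(53)] for lab in ("NOR", "MI")}
        g1, g2 = split_patients(ids, SplitSpec(seed=4))
        for lab in ("NOR", "MI"):
            assert len(g1[lab]) == 27 and len(g2[lab]) == 26
            assert not set(g1[lab]) & set(g2[lab])
        # 27 patients x 12 leads = 324 lead-records per class
        assert all(len(v) * 12 == 324 for v in g1.values())

    def test_insufficient_patients_rejected(self):
        ids = {"NOR": ["a", "b"], "MI": ["c", "d"]}
        with pytest.raises(InvalidArgumentError):
            split_patients(ids, SplitSpec())

    def test_patient_sets_disjoint_between_train_and_heldout(self):
        pid = [f"NOR{i}" for i in range(6) for _ in range(10)]
        pid += [f"MI{i}" for i in range(6) for _ in range(10)]
        lab = ["NOR"] * 60 + ["MI"] * 60
        table = _table(pid, lab)
        spec = SplitSpec(g1_patients_per_class=3, g2_patients_per_class=3, seed=1)
        res = inter_patient_split(table, spec)
        res.assert_inter_patient()  # must not raise
        train = set(res.train.patient_ids)
        held = set(res.validation.patient_ids) | set(res.test.patient_ids)
        assert not train & held

    def test_g2_published_counts_split_to_exact_test_counts(self):
        """12,135 NOR and 10,755 MI held-out segments at 20/80 give a test
        set of exactly 9,708 NOR and 8,604 MI."""
        spec = SplitSpec(seed=0)
        ids = {lab: [f"{lab}{i:03d}" for i in range(53)] for lab in ("NOR", "MI")}
        g1, g2 = split_patients(ids, spec)
        totals = {"NOR": 12135, "MI": 10755}
        pid, lab = [], []
        for label in ("NOR", "MI"):
            for p in g1[label]:  # sparse G1: content irrelevant here
                pid += [p] * 2
                lab += [label] * 2
            per, rem = divmod(totals[label], len(g2[label]))
            for j, p in enumerate(g2[label]):
                k = per + (1 if j < rem else 0)
                pid += [p] * k
                lab += [label] * k
        table = _table(pid, lab, n_features=1)
        res = inter_patient_split(table, spec)
        test_labels = pd.Series(res.test.labels).value_counts()
        assert test_labels["NOR"] == 9708
        assert test_labels["MI"] == 8604

    def test_validation_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            SplitSpec(validation_fraction=0.3, test_fraction=0.8)


class TestMetrics:
    def test_perfect_diagonal_all_ones(self):
        rec = metrics_from_confusion(ConfusionMatrix(np.diag([50, 70])))
        assert rec.accuracy == 1.0
        assert all(v == 1.0 for v in rec.precision.values())
        assert all(v == 1.0 for v in rec.recall.values())
        assert all(v == 1.0 for v in rec.f1.values())

    def test_fractional_counts_from_published_fractions(self):
        cm = ConfusionMatrix.from_fractions([[0.78, 0.22], [0.30, 0.70]],
                                            [9708, 8604])
        rec = metrics_from_confusion(cm).rounded()
        assert rec.accuracy == 0.74
        assert rec.precision["NOR"] == 0.75

    def test_accuracy_is_prevalence_weighted_recall(self, rng):
        counts = rng.integers(1, 500, size=(2, 2)).astype(float)
        cm = ConfusionMatrix(counts)
        rec = metrics_from_confusion(cm)
        prevalence = counts.sum(axis=1) / counts.sum()
        weighted = sum(prevalence[i] * rec.recall[lab]
                       for i, lab in enumerate(cm.labels))
        assert rec.accuracy == pytest.approx(weighted, abs=1e-12)

    def test_zero_denominator_reports_zero(self):
        # nothing predicted NOR -> precision undefined -> reported as 0
        rec = metrics_from_confusion(ConfusionMatrix([[0, 10], [0, 10]]))
        assert rec.precision["NOR"] == 0.0
        assert rec.f1["NOR"] == 0.0

    def test_round_half_up(self):
        assert round_half_up(0.735) == 0.74
        assert round_half_up(0.7349999) == 0.73
        assert round_half_up(0.665) == 0.67


class TestNormalizeConfusion:
    def test_simple_counts(self):
        out = normalize_confusion(ConfusionMatrix([[90, 10], [20, 80]]))
        assert np.allclose(out, [[0.9, 0.1], [0.2, 0.8]])

    def test_diagonal_normalizes_to_identity(self):
        out = normalize_confusion(ConfusionMatrix([[37, 0], [0, 112]]))
        assert np.allclose(out, np.eye(2))

    def test_rows_sum_to_one(self, rng):
        counts = rng.uniform(0.1, 100, size=(2, 2))
        out = normalize_confusion(ConfusionMatrix(counts))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_row_rejected(self):
        with pytest.raises(InvalidArgumentError):
            normalize_confusion(ConfusionMatrix([[0, 0], [1, 2]]))


@pytest.fixture(scope="module")
def tiny_models_and_test():
    rng = np.random.default_rng(5)
    n, d = 120, 130
    shift = np.zeros(d)
    shift[:5] = 2.5
    X = np.vstack([rng.normal(size=(n // 2, d)) - shift, rng.normal(size=(n // 2, d)) + shift])
    y = np.array(["NOR"] * (n // 2) + ["MI"] * (n // 2))
    models = {
        "SVM": fit(ModelSpec("SVM"), X, y),
        "KNN": fit(ModelSpec("KNN"), X, y),
        "RF": fit(ModelSpec("RF", {"n_estimators": 20}, rng_seed=0), X, y),
    }
    test = _table([f"P{i}" for i in range(40)],
                  ["NOR"] * 20 + ["MI"] * 20, n_features=d, seed=9)
    test.X[:20] -= shift
    test.X[20:] += shift
    return models, test


class TestRobustnessSweep:
    def test_grid_cardinality(self, tiny_models_and_test):
        models, test = tiny_models_and_test
        report = robustness_sweep(models, test, fs=200.0, seed=0)
        # 3 models x 3 noises x 4 SNRs plus 3 clean baselines
        assert len(report.entries) == 36 + 3
        assert all((m, "clean", None) in report.entries for m in models)

    def test_near_clean_snr_matches_clean_metrics(self, tiny_models_and_test):
        models, test = tiny_models_and_test
        report = robustness_sweep(models, test, snr_levels_db=(60.0,), fs=200.0, seed=1)
        for m in models:
            clean = report.accuracy(m, "clean", None)
            for kind in ("baseline_wander", "muscle_artifact", "electrode_motion"):
                assert abs(report.accuracy(m, kind, 60.0) - clean) <= 0.02

    def test_untrained_model_rejected(self, tiny_models_and_test):
        _, test = tiny_models_and_test
        from sklearn.svm import SVC
        with pytest.raises(InvalidStateError):
            robustness_sweep({"SVM": SVC()}, test)

    def test_report_frame_long_format(self, tiny_models_and_test):
        models, test = tiny_models_and_test
        report = robustness_sweep(models, test, snr_levels_db=(16.0,), fs=200.0, seed=2)
        frame = report.to_frame()
        assert {"model", "noise", "snr_db", "class", "precision", "recall",
                "f1", "accuracy"} <= set(frame.columns)
        assert len(frame) == len(report.entries) * 2  # one row per class
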