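"""Evaluation oracles: MCC formula, ROC/AUC, operating points, aggregation."""

import math

import numpy as np
import pytest

from drsmargin.evaluate import (
    ConfusionCounts,
    aggregate_iterations,
    confusion_counts,
    mcc,
    mcc_optimal_threshold,
    misclassification_scatter,
    optimal_operating_point,
    roc_curve,
)


class TestMCC:
    def test_perfect_agreement(self):
        assert mcc(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0

    def test_perfect_disagreement(self):
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=10, fn=10)) == -1.0

    def test_hand_computed_case(self):
        value = mcc(ConfusionCounts(tp=8, tn=7, fp=2, fn=3))
        assert value == pytest.approx((8 * 7 - 2 * 3) / math.sqrt(10 * 11 * 9 * 10))

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=10, fp=0, fn=0)) == 0.0

    def test_matches_reference_implementation_on_random_matrices(self, rng):
        """Direct-formula agreement with scikit-learn's MCC on >= 50 matrices."""
        from sklearn.metrics import matthews_corrcoef

        for _ in range(60):
            counts = rng.integers(0, 30, size=4)
            tp, tn, fp, fn = (int(c) for c in counts)
            if tp + fn == 0 or tn + fp == 0:
                continue
            y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            ours = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_class_swap_invariance_and_prediction_negation(self, rng):
        for _ in range(25):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 20, 4))
            base = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            swapped = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
            negated = mcc(ConfusionCounts(tp=fn, tn=fp, fp=tn, fn=tp))
            assert base == pytest.approx(swapped, abs=1e-12)
            assert negated == pytest.approx(-base, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestROC:
    def test_perfect_separation_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_curve(scores, labels).auc == pytest.approx(1.0)

    def test_null_labels_auc_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert 0.48 <= roc_curve(scores, labels).auc <= 0.52

    def test_reflection_symmetry(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_with_unit_endpoints(self, rng):
        curve = roc_curve(rng.random(200), rng.integers(0, 2, 200))
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))


class TestOperatingPoint:
    def test_perfect_curve_hits_corner(self):
        curve = roc_curve(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        thr, sens, spec = optimal_operating_point(curve, prevalence=0.5)
        assert sens == 1.0 and spec == 1.0

    def test_huge_fn_cost_forces_full_sensitivity(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        curve = roc_curve(scores, labels)
        _, sens, _ = optimal_operating_point(curve, cost_fn=1e9, prevalence=0.5)
        assert sens == 1.0

    def test_matches_brute_force_on_hand_built_curve(self):
        from drsmargin.evaluate import ROCCurve

        curve = ROCCurve(
            thresholds=np.array([np.inf, 0.8, 0.6, 0.4, 0.2]),
            fpr=np.array([0.0, 0.1, 0.3, 0.6, 1.0]),
            tpr=np.array([0.0, 0.5, 0.8, 0.9, 1.0]),
            auc=0.8,
        )
        cost_fp, cost_fn, prev = 2.0, 5.0, 0.3
        thr, sens, spec = optimal_operating_point(curve, cost_fp, cost_fn, prev)
        costs = cost_fp * curve.fpr * (1 - prev) + cost_fn * (1 - curve.tpr) * prev
        assert cost_fp * (1 - spec) * (1 - prev) + cost_fn * (1 - sens) * prev == pytest.approx(
            costs.min()
        )
        # exhaustive: chosen cost is <= every curve point's cost
        assert np.all(costs >= costs.min())


class TestMCCThreshold:
    def test_separable_scores_give_mcc_one(self):
        scores = np.array([0.9, 0.85, 0.2, 0.15, 0.1])
        labels = np.array([1, 1, 0, 0, 0])
        thr = mcc_optimal_threshold(scores, labels)
        assert mcc(confusion_counts(scores, labels, thr)) == 1.0

    def test_matches_exhaustive_scan(self, rng):
        scores = np.round(rng.random(8), 2)
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        thr = mcc_optimal_threshold(scores, labels)
        best = max(mcc(confusion_counts(scores, labels, t)) for t in np.unique(scores))
        assert mcc(confusion_counts(scores, labels, thr)) == pytest.approx(best)

    def test_degenerate_equal_scores_warn(self):
        with pytest.warns(UserWarning):
            thr = mcc_optimal_threshold(np.full(6, 0.5), np.array([0, 1] * 3))
        assert thr == 0.5

    def test_sensitivity_at_optimum_not_below_predict_all_healthy(self, rng):
        scores = rng.random(100)
        labels = (scores + rng.normal(0, 0.3, 100) > 0.5).astype(int)
        if np.unique(labels).size < 2:
            pytest.skip("degenerate draw")
        thr = mcc_optimal_threshold(scores, labels)
        c = confusion_counts(scores, labels, thr)
        sens = c.tp / (c.tp + c.fn)
        c_all_healthy = confusion_counts(scores, labels, np.inf)
        sens_trivial = c_all_healthy.tp / (c_all_healthy.tp + c_all_healthy.fn)
        assert sens >= sens_trivial


class TestAggregation:
    def test_identical_values_collapse(self):
        mean, sd, ci = aggregate_iterations(np.full(20, 0.7))
        assert mean == pytest.approx(0.7)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert ci[0] == pytest.approx(0.7) and ci[1] == pytest.approx(0.7)

    def test_known_sequence(self):
        mean, sd, ci = aggregate_iterations(np.arange(1.0, 21.0))
        assert mean == pytest.approx(10.5)
        assert sd == pytest.approx(np.std(np.arange(1, 21), ddof=1))
        assert ci[0] >= 1.0 and ci[1] <= 20.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_iterations(np.array([1.0]))


class TestMisclassificationScatter:
    def _truths(self):
        from drsmargin.simulate import GroundTruth

        out = {}
        for i, (pct, d) in enumerate([(80.0, 0.3), (50.0, 1.0), (20.0, 1.6), (5.0, 1.9)]):
            out[f"L{i}"] = GroundTruth(
                location_id=f"L{i}", tumor_pct=pct, fat_pct=(100 - pct) / 2,
                connective_pct=(100 - pct) / 2, label="malignant",
                margin_distance_min=d, margin_distance_central=d,
                margin_distance_max=d, margin_distance_mean=d,
            )
        return out

    def test_negative_correlation_and_correctness_flags(self):
        truths = self._truths()
        ids = np.array(["L0", "L1", "L2", "L3"])
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.ones(4, dtype=int)
        records, r = misclassification_scatter(ids, scores, labels, 0.5, truths)
        assert r < 0
        assert [rec["correct"] for rec in records] == [True, True, False, False]

    def test_single_malignant_location_r_absent(self):
        truths = self._truths()
        records, r = misclassification_scatter(
            np.array(["L0"]), np.array([0.9]), np.array([1]), 0.5, truths
        )
        assert r is None and len(records) == 1

    def test_all_correct_has_no_incorrect_records(self):
        truths = self._truths()
        ids = np.array(list(truths))
        records, _ = misclassification_scatter(
            ids, np.ones(4), np.ones(4, dtype=int), 0.5, truths
        )
        assert all(rec["correct"] for rec in records)
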