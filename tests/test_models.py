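"""CV planning, RUSBoost behavior, artifact contracts."""

import numpy as np
import pytest

from drsmargin.models import (
    Hyperparameters,
    make_cv_plan,
    rusboost_fit,
    rusboost_score,
    score,
    train,
)


@pytest.fixture(scope="module")
def blobs_90_10():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal([0, 0], 1.2, (450, 2)), rng.normal([2.2, 2.2], 1.2, (50, 2))])
    y = np.array([0] * 450 + [1] * 50)
    return X, y


class TestCVPlan:
    def test_balanced_partition_of_ten_patients(self):
        patients = [f"P{i}" for i in range(10)]
        malignant = {p: i < 3 for i, p in enumerate(patients)}
        with pytest.warns(UserWarning):  # 3 malignant patients < 5 folds
            plan = make_cv_plan(patients, malignant, n_folds=5, n_iterations=4, seed=0)
        for it in range(4):
            sizes = [len(plan.test_patients(it, f)) for f in range(5)]
            assert sizes == [2] * 5

    def test_determinism_under_seed(self):
        patients = [f"P{i}" for i in range(20)]
        malignant = {p: i % 4 == 0 for i, p in enumerate(patients)}
        a = make_cv_plan(patients, malignant, seed=3)
        b = make_cv_plan(patients, malignant, seed=3)
        assert a.assignments == b.assignments

    def test_100_patients_20_iterations_all_distinct(self):
        patients = [f"P{i}" for i in range(100)]
        malignant = {p: i < 12 for i, p in enumerate(patients)}
        plan = make_cv_plan(patients, malignant, n_iterations=20, seed=1)
        seen = {tuple(sorted(a.items())) for a in plan.assignments}
        assert len(seen) == 20

    def test_folds_partition_patients_with_no_overlap(self):
        patients = [f"P{i}" for i in range(17)]
        malignant = {p: i < 5 for i, p in enumerate(patients)}
        plan = make_cv_plan(patients, malignant, n_folds=5, n_iterations=3, seed=2)
        for it in range(3):
            for fold in range(5):
                tr = plan.train_patients(it, fold)
                te = plan.test_patients(it, fold)
                assert not (tr & te)
                assert tr | te == set(patients)

    def test_stratification_spreads_malignant_patients(self):
        patients = [f"P{i}" for i in range(25)]
        malignant = {p: i < 5 for i, p in enumerate(patients)}
        plan = make_cv_plan(patients, malignant, n_folds=5, n_iterations=5, seed=0)
        for it in range(5):
            for fold in range(5):
                assert sum(malignant[p] for p in plan.test_patients(it, fold)) == 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(["P0", "P1"], {"P0": True, "P1": False}, n_folds=5)

    def test_few_malignant_patients_warns(self):
        patients = [f"P{i}" for i in range(10)]
        malignant = {p: p == "P0" for p in patients}
        with pytest.warns(UserWarning):
            make_cv_plan(patients, malignant, n_folds=5, n_iterations=2, seed=0)


class TestRUSBoost:
    def test_single_round_on_balanced_data_is_one_tree(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        ens = rusboost_fit(X, y, n_rounds=1, seed=0)
        assert len(ens.trees) == 1
        s = rusboost_score(ens, X)
        assert np.array_equal(s, ens.trees[0].predict(X).astype(float))

    def test_identical_features_give_constant_scores(self):
        X = np.ones((60, 3))
        y = np.array([0] * 54 + [1] * 6)
        s = rusboost_score(rusboost_fit(X, y, seed=0), X)
        assert np.allclose(s, s[0])

    def test_minority_recall_beats_single_unbalanced_tree(self, blobs_90_10):
        from sklearn.tree import DecisionTreeClassifier

        X, y = blobs_90_10
        rng = np.random.default_rng(42)
        Xt = np.vstack([rng.normal([0, 0], 1.2, (450, 2)), rng.normal([2.2, 2.2], 1.2, (50, 2))])
        yt = np.array([0] * 450 + [1] * 50)
        ens = rusboost_fit(X, y, seed=1)
        recall_rus = np.mean((rusboost_score(ens, Xt) >= 0.5)[yt == 1])
        tree = DecisionTreeClassifier(max_depth=5, random_state=1).fit(X, y)
        recall_tree = np.mean(tree.predict(Xt)[yt == 1] == 1)
        assert recall_rus > recall_tree

    def test_training_error_non_increasing_to_plateau(self, blobs_90_10):
        X, y = blobs_90_10
        errs = []
        for rounds in (1, 5, 20, 60):
            ens = rusboost_fit(X, y, n_rounds=rounds, seed=3)
            errs.append(float(np.mean((rusboost_score(ens, X) >= 0.5) != y)))
        assert errs[-1] <= errs[0]
        assert min(errs) == errs[-1] or errs[-1] - min(errs) < 0.02

    def test_scores_in_unit_interval(self, blobs_90_10):
        X, y = blobs_90_10
        s = rusboost_score(rusboost_fit(X, y, seed=5), X)
        assert np.all((s >= 0) & (s <= 1))

    def test_empty_minority_rejected(self):
        with pytest.raises(ValueError):
            rusboost_fit(np.ones((10, 2)), np.zeros(10), seed=0)

    def test_determinism(self, blobs_90_10):
        X, y = blobs_90_10
        s1 = rusboost_score(rusboost_fit(X, y, seed=9), X)
        s2 = rusboost_score(rusboost_fit(X, y, seed=9), X)
        assert np.array_equal(s1, s2)


@pytest.fixture(scope="module")
def trained(small_tensor, small_labels):
    return {
        mt: train(mt, small_tensor, small_labels, seed=0)
        for mt in ("linear_svm", "quadratic_svm", "weighted_knn", "rusboost")
    }


class TestArtifacts:
    def test_training_scores_reproducible(self, trained, small_tensor):
        for mt, art in trained.items():
            again = art.score_spectra(small_tensor)
            assert np.array_equal(again, art.training_scores), mt

    def test_scores_bounded_and_ordered_by_class(self, trained, small_tensor, small_labels):
        for mt, art in trained.items():
            s = art.score_spectra(small_tensor)
            assert np.all((s >= 0) & (s <= 1)), mt
            assert s[small_labels == 1].mean() > s[small_labels == 0].mean(), mt

    def test_retrain_same_seed_identical(self, small_tensor, small_labels):
        a = train("rusboost", small_tensor, small_labels, seed=4)
        b = train("rusboost", small_tensor, small_labels, seed=4)
        assert np.array_equal(a.training_scores, b.training_scores)

    def test_score_order_invariance(self, trained, small_cohort):
        measurements, _ = small_cohort
        art = trained["linear_svm"]
        fwd = score(art, measurements[:6])
        rev = score(art, measurements[:6][::-1])
        assert np.allclose(fwd, rev[::-1])

    def test_single_class_training_rejected(self, small_tensor):
        with pytest.raises(ValueError):
            train("linear_svm", small_tensor, np.zeros(small_tensor.shape[0]), seed=0)

    def test_unknown_model_type_rejected(self, small_tensor, small_labels):
        with pytest.raises(ValueError):
            train("random_forest", small_tensor, small_labels, seed=0)

    def test_separable_toy_problem_all_models_fit_training_data(self):
        """On well-separated synthetic classes every family reaches high
        training accuracy."""
        import drsmargin as dm
        from drsmargin.models import spectra_tensor

        cfg = dm.well_separated_config(seed=5)
        cfg = dm.SimulationConfig(
            n_patients=10, locations_per_patient=4, tumor_location_rate=0.5,
            priors=cfg.priors, noise=cfg.noise, tumor_signal_floor=cfg.tumor_signal_floor,
            seed=5,
        )
        ms, ts = dm.simulate_cohort(cfg)
        tensor = spectra_tensor(ms)
        labels = np.array([t.label == "malignant" for t in ts]).astype(int)
        for mt in ("linear_svm", "quadratic_svm", "weighted_knn", "rusboost"):
            art = train(mt, tensor, labels, seed=0)
            acc = np.mean((art.training_scores >= 0.5) == labels)
            assert acc >= 0.95, mt
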