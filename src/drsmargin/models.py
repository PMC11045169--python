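"""Classifier training under patient-grouped repeated cross-validation.

Four model families are supported: linear SVM, quadratic (degree-2
polynomial) SVM, weighted (inverse-distance) k-nearest neighbours, and
RUSBoost.  The first three delegate to scikit-learn; RUSBoost — an
AdaBoost variant that random-undersamples the majority class before each
weak-learner fit, the method of choice for the strong class imbalance of
margin data — is implemented here on top of depth-limited decision trees.

Cross-validation is patient-grouped: every location of a patient lands in
the same fold, because locations of one patient share tissue composition
(a patient-level random effect in the simulator, biology in the clinic).
Test sets always contain in vivo locations only; the training regime
controls whether ex vivo, in vivo, or both kinds of locations are used
for fitting.

A fitted ``ModelArtifact`` bundles everything test-time scoring needs:
the MSC reference (fitted on training spectra only), the selected feature
names, the feature scaler, and the classifier itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import features as feats
from . import mrmr
from .preprocess import MSCReference, fit_msc_reference, msc_normalize, preprocess_measurement
from .simulate import RawMeasurement

__all__ = [
    "MODEL_TYPES",
    "REGIMES",
    "CVPlan",
    "Hyperparameters",
    "ModelArtifact",
    "RUSBoostEnsemble",
    "make_cv_plan",
    "rusboost_fit",
    "rusboost_score",
    "train",
    "score",
    "spectra_tensor",
]

MODEL_TYPES = ("linear_svm", "quadratic_svm", "weighted_knn", "rusboost")
REGIMES = ("ex_vivo_only", "in_vivo_only", "both")


@dataclass(frozen=True)
class CVPlan:
    """Per-iteration patient -> fold assignments for repeated grouped CV."""

    n_folds: int
    n_iterations: int
    seed: int
    assignments: tuple[dict[str, int], ...]

    def test_patients(self, iteration: int, fold: int) -> set[str]:
        return {p for p, f in self.assignments[iteration].items() if f == fold}

    def train_patients(self, iteration: int, fold: int) -> set[str]:
        return {p for p, f in self.assignments[iteration].items() if f != fold}


def make_cv_plan(
    patients: Sequence[str],
    patient_malignant: dict[str, bool],
    n_folds: int = 5,
    n_iterations: int = 20,
    seed: int = 0,
) -> CVPlan:
    """Random patient partitions, stratified by patient-level malignancy.

    Patients with at least one malignant location are dealt round-robin
    across folds (so every fold holds malignant patients whenever there are
    at least ``n_folds`` of them), then the healthy patients likewise.
    Iterations draw independent partitions from sub-generators spawned off
    the single plan seed.
    """
    unique = list(dict.fromkeys(patients))
    if len(unique) < n_folds:
        raise ValueError(f"need >= {n_folds} patients, got {len(unique)}")
    malignant = [p for p in unique if patient_malignant.get(p, False)]
    healthy = [p for p in unique if not patient_malignant.get(p, False)]
    if not malignant or not healthy:
        raise ValueError("both classes must be present at the patient level")
    if len(malignant) < n_folds:
        import warnings

        warnings.warn(
            f"only {len(malignant)} malignant patients for {n_folds} folds; "
            "stratification is best-effort",
            stacklevel=2,
        )
    root = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_iterations):
        sub = np.random.default_rng(root.integers(0, 2**31))
        mapping: dict[str, int] = {}
        i = 0
        # one continuous round-robin deal across both strata keeps folds
        # balanced and guarantees every fold is nonempty
        for group in (malignant, healthy):
            order = list(group)
            sub.shuffle(order)
            for p in order:
                mapping[p] = i % n_folds
                i += 1
        assignments.append(mapping)
    return CVPlan(
        n_folds=n_folds, n_iterations=n_iterations, seed=seed, assignments=tuple(assignments)
    )


# ---------------------------------------------------------------------------
# RUSBoost


@dataclass(frozen=True)
class RUSBoostEnsemble:
    """Boosted ensemble of depth-limited trees fitted on undersampled draws."""

    trees: tuple[DecisionTreeClassifier, ...]
    alphas: tuple[float, ...]
    round_errors: tuple[float, ...]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Alpha-weighted vote share for the malignant class, in [0, 1].

        score(x) = sum_t alpha_t * h_t(x) / sum_t alpha_t with hard tree
        predictions h_t in {0, 1}; thresholding at 0.5 is the classical
        weighted-majority boosting decision.
        """
        X = np.asarray(X, float)
        total = sum(self.alphas)
        if total <= 0:
            return np.full(X.shape[0], 0.5)
        acc = np.zeros(X.shape[0])
        for tree, alpha in zip(self.trees, self.alphas):
            acc += alpha * tree.predict(X)
        return acc / total


def rusboost_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_rounds: int = 100,
    learning_rate: float = 0.1,
    max_depth: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    max_retries: int = 10,
) -> RUSBoostEnsemble:
    """Fit RUSBoost: random undersampling of the majority class + boosting.

    Per round, a balanced training draw is formed by keeping every minority
    example and sampling majority examples *without replacement with
    probability proportional to their current boosting weight* until the
    target minority:majority ratio (default 1:1) is met.  A depth-limited
    tree is fitted on the draw, its weighted error ``eps`` is measured on
    the full weighted training set, rounds with ``eps >= 0.5`` are
    discarded and resampled, and weights are updated AdaBoost-style with
    ``alpha = learning_rate * ln((1 - eps) / eps)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("rusboost_fit requires exactly two classes in y")
    minority = classes[np.argmin(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    if min_idx.size == 0:
        raise ValueError("minority class is empty")

    rng = np.random.default_rng(seed)
    n = y.size
    w = np.full(n, 1.0 / n)
    trees: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    errors: list[float] = []

    n_keep = min(maj_idx.size, max(1, int(round(min_idx.size / target_ratio))))
    for t in range(n_rounds):
        for attempt in range(max_retries):
            w_maj = w[maj_idx]
            p = w_maj / w_maj.sum() if w_maj.sum() > 0 else None
            chosen_maj = rng.choice(maj_idx, size=n_keep, replace=False, p=p)
            sample = np.concatenate([min_idx, chosen_maj])
            tree = DecisionTreeClassifier(
                max_depth=max_depth, random_state=int(rng.integers(0, 2**31))
            )
            tree.fit(X[sample], y[sample], sample_weight=w[sample])
            pred = tree.predict(X)
            eps = float(w[pred != y].sum() / w.sum())
            if eps < 0.5:
                break
        else:
            break  # no useful weak learner found; stop boosting
        eps_c = min(max(eps, 1e-10), 1 - 1e-10)
        alpha = learning_rate * np.log((1.0 - eps_c) / eps_c)
        trees.append(tree)
        alphas.append(float(alpha))
        errors.append(eps)
        w = w * np.exp(alpha * (pred != y))
        w = w / w.sum()
    if not trees:
        raise RuntimeError("RUSBoost failed to fit any round with error < 0.5")
    return RUSBoostEnsemble(trees=tuple(trees), alphas=tuple(alphas), round_errors=tuple(errors))


def rusboost_score(ensemble: RUSBoostEnsemble, X: np.ndarray) -> np.ndarray:
    return ensemble.decision_scores(X)


# ---------------------------------------------------------------------------
# Model artifacts


@dataclass(frozen=True)
class Hyperparameters:
    """Defaults for all four model families; every field is overridable."""

    svm_c: float = 1.0
    knn_k: int = 10
    rus_rounds: int = 100
    rus_learning_rate: float = 0.1
    rus_max_depth: int = 5
    rus_target_ratio: float = 1.0


@dataclass
class ModelArtifact:
    """Self-contained fitted pipeline state for test-time scoring."""

    model_type: str
    msc_reference: MSCReference
    selected_features: tuple[str, ...]
    selected_indices: np.ndarray
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    estimator: object
    platt: LogisticRegression | None
    ranking: mrmr.FeatureRanking
    ranges: tuple[feats.FeatureRange, ...]
    seed: int
    training_scores: np.ndarray | None = None
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)

    def score_features(self, feature_matrix: np.ndarray) -> np.ndarray:
        """Continuous malignancy score in [0, 1] from a raw feature table."""
        Xs = (feature_matrix[:, self.selected_indices] - self.scaler_mean) / self.scaler_std
        if self.model_type == "rusboost":
            return rusboost_score(self.estimator, Xs)
        if self.model_type == "weighted_knn":
            proba = self.estimator.predict_proba(Xs)
            return proba[:, list(self.estimator.classes_).index(1)]
        margin = self.estimator.decision_function(Xs)
        return self.platt.predict_proba(margin[:, None])[:, 1]

    def score_spectra(self, tensor: np.ndarray) -> np.ndarray:
        """Score (n_locations, 5, 1200) pre-MSC spectra end to end."""
        X = _feature_table(tensor, self.msc_reference, self.ranges)
        return self.score_features(X)


def spectra_tensor(measurements: Sequence[RawMeasurement]) -> np.ndarray:
    """Preprocess raw measurements into an (n, 5, 1200) pre-MSC tensor."""
    out = np.empty((len(measurements), 5, 1200))
    for i, m in enumerate(measurements):
        for j, s in enumerate(preprocess_measurement(m)):
            out[i, j] = s.intensities
    return out


def _feature_table(
    tensor: np.ndarray, reference: MSCReference, ranges: tuple[feats.FeatureRange, ...]
) -> np.ndarray:
    """MSC-normalize an (n, 5, 1200) tensor and extract the 400 features."""
    from scipy.signal import savgol_filter

    n = tensor.shape[0]
    flat = tensor.reshape(n * 5, -1)
    corrected = msc_normalize(flat, reference)
    d2 = savgol_filter(corrected, 11, 2, deriv=2, axis=-1)
    blocks = [feats.range_feature_matrix(corrected, r, d2=d2) for r in ranges]
    per_spectrum = np.stack(blocks, axis=1).reshape(n * 5, -1)  # (n*5, 16*5)
    return per_spectrum.reshape(n, -1)  # fiber-major 400-vector per location


def train(
    model_type: str,
    tensor: np.ndarray,
    labels: np.ndarray,
    hyper: Hyperparameters | None = None,
    ranges: tuple[feats.FeatureRange, ...] = feats.DEFAULT_RANGES,
    mrmr_bins: int = mrmr.DEFAULT_BINS,
    mrmr_threshold: float = mrmr.DEFAULT_THRESHOLD,
    seed: int = 0,
) -> ModelArtifact:
    """Fit one model on pre-MSC training spectra.

    ``tensor`` is (n_locations, 5 fibers, 1200); ``labels`` is binary with
    1 = malignant.  All data-dependent state (MSC reference, MRMR
    selection, feature scaling) is fitted on this training data only and
    frozen into the returned artifact.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    hyper = hyper or Hyperparameters()
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")

    n = tensor.shape[0]
    reference = fit_msc_reference(tensor.reshape(n * 5, -1))
    X = _feature_table(tensor, reference, ranges)
    names = feats.feature_names(ranges)

    ranking = mrmr.mrmr_rank(X, y, names=list(names), n_bins=mrmr_bins, threshold=mrmr_threshold)
    selected = mrmr.apply_threshold(ranking)
    if not selected:
        raise ValueError("MRMR selected zero features; refusing to train")
    name_to_idx = {nm: i for i, nm in enumerate(names)}
    sel_idx = np.array([name_to_idx[nm] for nm in selected])

    Xs_raw = X[:, sel_idx]
    mean = Xs_raw.mean(axis=0)
    std = Xs_raw.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    Xs = (Xs_raw - mean) / std

    platt = None
    if model_type == "linear_svm":
        est = SVC(kernel="linear", C=hyper.svm_c, random_state=seed)
        est.fit(Xs, y)
        platt = _fit_platt(est.decision_function(Xs), y)
    elif model_type == "quadratic_svm":
        est = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=hyper.svm_c, random_state=seed)
        est.fit(Xs, y)
        platt = _fit_platt(est.decision_function(Xs), y)
    elif model_type == "weighted_knn":
        k = min(hyper.knn_k, n)
        est = KNeighborsClassifier(n_neighbors=k, weights="distance")
        est.fit(Xs, y)
    else:
        est = rusboost_fit(
            Xs,
            y,
            n_rounds=hyper.rus_rounds,
            learning_rate=hyper.rus_learning_rate,
            max_depth=hyper.rus_max_depth,
            target_ratio=hyper.rus_target_ratio,
            seed=seed,
        )

    artifact = ModelArtifact(
        model_type=model_type,
        msc_reference=reference,
        selected_features=selected,
        selected_indices=sel_idx,
        scaler_mean=mean,
        scaler_std=std,
        estimator=est,
        platt=platt,
        ranking=ranking,
        ranges=ranges,
        seed=seed,
        hyperparameters=hyper,
    )
    artifact.training_scores = artifact.score_features(X)
    return artifact


def _fit_platt(margins: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Platt-style sigmoid calibration of SVM decision values."""
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(margins[:, None], y)
    return lr


def score(artifact: ModelArtifact, measurements: Sequence[RawMeasurement]) -> np.ndarray:
    """Score raw measurements with a fitted artifact (order-invariant)."""
    tensor = spectra_tensor(measurements)
    return artifact.score_spectra(tensor)
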