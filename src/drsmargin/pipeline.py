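"""The margin-classification model object and its cross-validated results.

The public surface follows the fitted-model convention of the statistical
Python stack: a :class:`MarginClassification` object is built from a
cohort (raw measurements + ground truth), ``fit()`` runs the full
analysis — preprocessing, per-fold MSC, feature extraction, per-fold MRMR
selection, classifier training under patient-grouped repeated 5-fold CV —
and returns a :class:`MarginClassificationResults` carrying the score
table, MCC mean/SD over iterations, pooled ROC/AUC, both operating
points, sensitivity/specificity with percentile CIs, the modal feature
selection, and the misclassification scatter.  ``summary()`` renders a
text table; plotting hangs off the results object.

``run_experiment`` orchestrates the full model-type x training-regime
grid into a reproducible run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import features as feats
from . import mrmr
from .models import (
    MODEL_TYPES,
    REGIMES,
    CVPlan,
    Hyperparameters,
    make_cv_plan,
    spectra_tensor,
    train,
)
from .simulate import GroundTruth, RawMeasurement, SimulationConfig, simulate_cohort

__all__ = [
    "MarginClassification",
    "MarginClassificationResults",
    "RunConfig",
    "run_experiment",
]

logger = logging.getLogger("drsmargin")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one experiment run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model_types: tuple[str, ...] = MODEL_TYPES
    regimes: tuple[str, ...] = REGIMES
    n_folds: int = 5
    n_iterations: int = 20
    mrmr_bins: int = mrmr.DEFAULT_BINS
    mrmr_threshold: float = mrmr.DEFAULT_THRESHOLD
    decision_threshold: float = 0.5
    cost_fp: float = 1.0
    cost_fn: float = 1.0
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .simulate import CompositionPriors, NoiseConfig

        kwargs = dict(raw)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], dict):
            sim = dict(kwargs["simulation"])
            if isinstance(sim.get("priors"), dict):
                priors = dict(sim["priors"])
                for key in ("healthy_mean", "tumor_mean", "in_vivo_so2", "ex_vivo_so2"):
                    if key in priors:
                        priors[key] = tuple(priors[key])
                sim["priors"] = CompositionPriors(**priors)
            if isinstance(sim.get("noise"), dict):
                sim["noise"] = NoiseConfig(**sim["noise"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if isinstance(kwargs.get("hyperparameters"), dict):
            kwargs["hyperparameters"] = Hyperparameters(**kwargs["hyperparameters"])
        for key in ("model_types", "regimes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class MarginClassification:
    """A margin classifier specified on a cohort, before fitting.

    Parameters
    ----------
    measurements, truths
        The cohort: one raw five-fiber measurement and one ground-truth
        record per probed location, aligned by ``location_id``.
    model_type
        One of ``linear_svm``, ``quadratic_svm``, ``weighted_knn``,
        ``rusboost``.
    regime
        Training-data regime: ``ex_vivo_only``, ``in_vivo_only`` or
        ``both``.  The test set always consists of in vivo locations.
    """

    def __init__(
        self,
        measurements: Sequence[RawMeasurement],
        truths: Sequence[GroundTruth],
        model_type: str = "rusboost",
        regime: str = "both",
        hyperparameters: Hyperparameters | None = None,
        ranges: tuple[feats.FeatureRange, ...] = feats.DEFAULT_RANGES,
        mrmr_bins: int = mrmr.DEFAULT_BINS,
        mrmr_threshold: float = mrmr.DEFAULT_THRESHOLD,
        decision_threshold: float = 0.5,
        cost_fp: float = 1.0,
        cost_fn: float = 1.0,
    ) -> None:
        if model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model type {model_type!r}")
        if regime not in REGIMES:
            raise ValueError(f"unknown regime {regime!r}")
        truth_by_loc = {t.location_id: t for t in truths}
        missing = [m.location_id for m in measurements if m.location_id not in truth_by_loc]
        if missing:
            raise ValueError(f"no ground truth for location(s): {missing[:3]}...")
        self.measurements = list(measurements)
        self.truths = truth_by_loc
        self.model_type = model_type
        self.regime = regime
        self.hyper = hyperparameters or Hyperparameters()
        self.ranges = ranges
        self.mrmr_bins = mrmr_bins
        self.mrmr_threshold = mrmr_threshold
        self.decision_threshold = decision_threshold
        self.cost_fp = cost_fp
        self.cost_fn = cost_fn

        self.location_ids = np.array([m.location_id for m in self.measurements])
        self.patient_ids = np.array([m.patient_id for m in self.measurements])
        self.contexts = np.array([m.context for m in self.measurements])
        self.labels = np.array(
            [1 if truth_by_loc[m.location_id].label == "malignant" else 0 for m in self.measurements]
        )
        self._tensor: np.ndarray | None = None

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig | None = None, **kwargs
    ) -> "MarginClassification":
        """Build the model on a freshly simulated cohort."""
        config = config or SimulationConfig()
        measurements, truths = simulate_cohort(config)
        return cls(measurements, truths, **kwargs)

    @property
    def tensor(self) -> np.ndarray:
        """(n_locations, 5, 1200) stitched & trimmed (pre-MSC) spectra, cached."""
        if self._tensor is None:
            self._tensor = spectra_tensor(self.measurements)
        return self._tensor

    def fit(
        self, n_folds: int = 5, n_iterations: int = 20, seed: int = 0
    ) -> "MarginClassificationResults":
        """Run patient-grouped repeated k-fold CV and collect all scores.

        Every in vivo location is scored exactly once per iteration, by the
        model whose training fold excluded that location's patient.  MSC
        reference, MRMR selection and feature scaling are refitted inside
        each training fold.
        """
        patient_malignant: dict[str, bool] = {}
        for pid, lab in zip(self.patient_ids, self.labels):
            patient_malignant[pid] = patient_malignant.get(pid, False) or bool(lab)
        plan = make_cv_plan(
            list(self.patient_ids), patient_malignant, n_folds, n_iterations, seed
        )

        in_vivo = self.contexts == "in_vivo"
        regime_ok = {
            "ex_vivo_only": self.contexts == "ex_vivo",
            "in_vivo_only": in_vivo,
            "both": np.ones_like(in_vivo, dtype=bool),
        }[self.regime]

        rows = []
        per_fold_selected: list[tuple[str, ...]] = []
        rng = np.random.default_rng(seed)
        for it in range(n_iterations):
            for fold in range(plan.n_folds):
                test_patients = plan.test_patients(it, fold)
                train_patients = plan.train_patients(it, fold)
                assert not (test_patients & train_patients), "patient leakage across folds"
                test_mask = np.isin(self.patient_ids, list(test_patients)) & in_vivo
                train_mask = np.isin(self.patient_ids, list(train_patients)) & regime_ok
                if not test_mask.any():
                    continue
                if np.unique(self.labels[train_mask]).size < 2:
                    logger.warning(
                        "iteration %d fold %d: single-class training set, fold skipped", it, fold
                    )
                    continue
                artifact = train(
                    self.model_type,
                    self.tensor[train_mask],
                    self.labels[train_mask],
                    hyper=self.hyper,
                    ranges=self.ranges,
                    mrmr_bins=self.mrmr_bins,
                    mrmr_threshold=self.mrmr_threshold,
                    seed=int(rng.integers(0, 2**31)),
                )
                per_fold_selected.append(artifact.selected_features)
                scores = artifact.score_spectra(self.tensor[test_mask])
                for loc, pid, lab, s in zip(
                    self.location_ids[test_mask],
                    self.patient_ids[test_mask],
                    self.labels[test_mask],
                    scores,
                ):
                    rows.append(
                        {
                            "location_id": loc,
                            "patient_id": pid,
                            "iteration": it,
                            "fold": fold,
                            "label": int(lab),
                            "score": float(s),
                            "predicted": int(s >= self.decision_threshold),
                        }
                    )
        score_table = pd.DataFrame(rows)
        if score_table.empty:
            raise RuntimeError("cross-validation produced no test scores")
        return MarginClassificationResults(
            model=self,
            plan=plan,
            score_table=score_table,
            per_fold_selected=per_fold_selected,
            seed=seed,
        )


class MarginClassificationResults:
    """Cross-validated results of one model type under one regime."""

    def __init__(
        self,
        model: MarginClassification,
        plan: CVPlan,
        score_table: pd.DataFrame,
        per_fold_selected: list[tuple[str, ...]],
        seed: int,
    ) -> None:
        self.model = model
        self.plan = plan
        self.score_table = score_table
        self.per_fold_selected = per_fold_selected
        self.seed = seed
        self._compute()

    def _compute(self) -> None:
        df = self.score_table
        thr = self.model.decision_threshold

        per_iter_mcc = []
        per_iter_auc = []
        for _, g in df.groupby("iteration"):
            c = ev.confusion_counts(g["score"].to_numpy(), g["label"].to_numpy(), thr)
            per_iter_mcc.append(ev.mcc(c))
            if np.unique(g["label"]).size == 2:
                per_iter_auc.append(ev.roc_curve(g["score"].to_numpy(), g["label"].to_numpy()).auc)
        self.per_iteration_mcc = np.array(per_iter_mcc)
        self.per_iteration_auc = np.array(per_iter_auc)
        if self.per_iteration_mcc.size >= 2:
            self.mcc_mean, self.mcc_sd, self.mcc_ci = ev.aggregate_iterations(self.per_iteration_mcc)
        else:
            self.mcc_mean = float(self.per_iteration_mcc.mean())
            self.mcc_sd, self.mcc_ci = 0.0, (self.mcc_mean, self.mcc_mean)

        scores = df["score"].to_numpy()
        labels = df["label"].to_numpy()
        self.roc = ev.roc_curve(scores, labels)
        self.auc = self.roc.auc
        prevalence = float(labels.mean())
        self.operating_point = ev.optimal_operating_point(
            self.roc, self.model.cost_fp, self.model.cost_fn, prevalence
        )
        self.mcc_threshold = ev.mcc_optimal_threshold(scores, labels)

        op_thr = self.operating_point[0]
        sens, spec = [], []
        for _, g in df.groupby("iteration"):
            c = ev.confusion_counts(g["score"].to_numpy(), g["label"].to_numpy(), op_thr)
            if c.tp + c.fn:
                sens.append(c.tp / (c.tp + c.fn))
            if c.tn + c.fp:
                spec.append(c.tn / (c.tn + c.fp))
        self.sensitivity = float(np.mean(sens)) if sens else float("nan")
        self.specificity = float(np.mean(spec)) if spec else float("nan")
        self.sensitivity_ci = (
            tuple(np.percentile(sens, [2.5, 97.5])) if len(sens) >= 2 else (self.sensitivity,) * 2
        )
        self.specificity_ci = (
            tuple(np.percentile(spec, [2.5, 97.5])) if len(spec) >= 2 else (self.specificity,) * 2
        )

        self.selected_features = mrmr.modal_selection(self.per_fold_selected)

        # misclassification analysis on per-location mean scores
        mean_scores = df.groupby("location_id").agg(
            score=("score", "mean"), label=("label", "first")
        )
        self.scatter_records, self.distance_correlation = ev.misclassification_scatter(
            mean_scores.index.to_numpy(),
            mean_scores["score"].to_numpy(),
            mean_scores["label"].to_numpy(),
            op_thr,
            self.model.truths,
        )

    def summary(self) -> str:
        """Human-readable results table."""
        m = self.model
        op_thr, op_sens, op_spec = self.operating_point
        lines = [
            "Margin classification results (patient-grouped repeated CV)",
            "=" * 62,
            f"model type:            {m.model_type}",
            f"training regime:       {m.regime}",
            f"folds x iterations:    {self.plan.n_folds} x {self.plan.n_iterations}",
            f"locations (in vivo test pool): {int(self.score_table['location_id'].nunique())}",
            f"malignant prevalence (test):   {self.score_table['label'].mean():.3f}",
            "-" * 62,
            f"MCC (mean over iterations):    {self.mcc_mean:.3f} (SD {self.mcc_sd:.3f})",
            f"AUC (pooled scores):           {self.auc:.3f}",
            f"cost-optimal operating point:  threshold {op_thr:.3f}",
            f"  sensitivity:  {100 * self.sensitivity:.1f}% "
            f"(95% CI {100 * self.sensitivity_ci[0]:.1f}% to {100 * self.sensitivity_ci[1]:.1f}%)",
            f"  specificity:  {100 * self.specificity:.1f}% "
            f"(95% CI {100 * self.specificity_ci[0]:.1f}% to {100 * self.specificity_ci[1]:.1f}%)",
            f"MCC-optimal threshold:         {self.mcc_threshold:.3f}",
            f"selected features (modal, n={len(self.selected_features)}):",
        ]
        for name in self.selected_features[:10]:
            lines.append(f"  {name}")
        if len(self.selected_features) > 10:
            lines.append(f"  ... and {len(self.selected_features) - 10} more")
        if self.distance_correlation is not None:
            lines.append(
                f"tumor% vs margin-distance Pearson r: {self.distance_correlation:.3f}"
            )
        return "\n".join(lines)

    def report_row(self) -> dict:
        """One flat record for the model x regime report table."""
        return {
            "model_type": self.model.model_type,
            "regime": self.model.regime,
            "mcc_mean": self.mcc_mean,
            "mcc_sd": self.mcc_sd,
            "auc": self.auc,
            "op_threshold": self.operating_point[0],
            "sensitivity": self.sensitivity,
            "sensitivity_ci_lo": self.sensitivity_ci[0],
            "sensitivity_ci_hi": self.sensitivity_ci[1],
            "specificity": self.specificity,
            "specificity_ci_lo": self.specificity_ci[0],
            "specificity_ci_hi": self.specificity_ci[1],
            "mcc_optimal_threshold": self.mcc_threshold,
            "n_selected_features": len(self.selected_features),
            "distance_correlation": self.distance_correlation,
        }

    def plot_roc(self, ax=None):
        """ROC curve of the pooled cross-validated scores."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"{self.model.model_type} / {self.model.regime}")
        ax.legend()
        return ax

    def plot_misclassification(self, ax=None):
        """Tumor percentage vs margin distance, split by classification."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for correct, marker, color in ((True, "o", "tab:green"), (False, "x", "tab:red")):
            pts = [r for r in self.scatter_records if r["correct"] == correct]
            ax.scatter(
                [r["margin_distance_mean"] for r in pts],
                [r["tumor_pct"] for r in pts],
                marker=marker,
                color=color,
                label="correct" if correct else "misclassified",
            )
        ax.set_xlabel("mean tumor-margin distance (mm)")
        ax.set_ylabel("tumor area percentage in 2-mm band")
        ax.legend()
        return ax


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full model-type x regime grid into a run directory.

    Writes the resolved config, per-combination report rows (CSV + JSON),
    score tables, ROC points, modal feature selections, and stage timing
    logs.  Every report row carries the config hash.  Deterministic under
    the config's seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    chash = config.config_hash

    t0 = time.time()
    measurements, truths = simulate_cohort(config.simulation)
    logger.info("simulate: %d locations in %.1fs", len(measurements), time.time() - t0)

    report_rows = []
    shared_tensor: np.ndarray | None = None
    for model_type in config.model_types:
        for regime in config.regimes:
            t1 = time.time()
            model = MarginClassification(
                measurements,
                truths,
                model_type=model_type,
                regime=regime,
                hyperparameters=config.hyperparameters,
                mrmr_bins=config.mrmr_bins,
                mrmr_threshold=config.mrmr_threshold,
                decision_threshold=config.decision_threshold,
                cost_fp=config.cost_fp,
                cost_fn=config.cost_fn,
            )
            if shared_tensor is None:
                shared_tensor = model.tensor
            else:
                model._tensor = shared_tensor
            res = model.fit(
                n_folds=config.n_folds, n_iterations=config.n_iterations, seed=config.seed
            )
            row = res.report_row()
            row["config_hash"] = chash
            row["seed"] = config.seed
            report_rows.append(row)
            stem = f"{model_type}__{regime}"
            res.score_table.to_csv(out / f"scores_{stem}.csv", index=False)
            from .io import write_roc_csv

            write_roc_csv(res.roc.fpr, res.roc.tpr, res.roc.thresholds, out / f"roc_{stem}.csv")
            (out / f"selected_{stem}.json").write_text(
                json.dumps(list(res.selected_features), indent=2)
            )
            logger.info(
                "%s / %s: MCC %.3f AUC %.3f (%.1fs)",
                model_type, regime, res.mcc_mean, res.auc, time.time() - t1,
            )
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(json.dumps(report_rows, indent=2, default=float))
    return out
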