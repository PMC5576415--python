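"""Repeated stratified k-fold cross-validation and performance statistics.

Each run partitions the subjects into k stratified folds (per-fold class
counts within one of perfect proportionality).  Inside every fold the whole
model chain — PCA, optional LDA, Twin SVM — is refit on the training folds
only, so no test subject influences the model that scores it.  Per-run
statistics pool the confusion counts over folds (ratios of totals, not
averages of ratios); the summary reports mean +- sd across runs, and the
per-fold accuracy table is kept run-wise and fold-wise.

The seven statistics are the usual confusion-matrix ratios:
accuracy, sensitivity (= recall), specificity, precision, F-measure and
g-mean = sqrt(sensitivity * specificity).  Ratios with zero denominators
(a fold without one class) are reported as NaN, excluded from means, and
logged — never raised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dimred import lda_fit, lda_transform, max_components, pca_fit, pca_transform
from .features import FeatureMatrix, build_feature_matrix
from .io_preprocess import SubjectStack
from .twinsvm import TSVMModel, TSVMProblem, tsvm_fit, tsvm_predict

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "CVPlan",
    "PipelineConfig",
    "MetricsReport",
    "make_cv_plan",
    "compute_metrics",
    "fit_pipeline_fold",
    "run_pipeline_cv",
]

METRIC_NAMES = (
    "accuracy", "sensitivity", "specificity", "precision",
    "recall", "f_measure", "gmean",
)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else np.nan


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The seven statistics; undefined ratios come back as NaN."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    f = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else np.nan
    )
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f_measure": f,
        "gmean": float(np.sqrt(sens * spec)) if np.isfinite(sens) and np.isfinite(spec) else np.nan,
    }


@dataclass
class CVPlan:
    k: int
    runs: int
    seed: int
    fold_assignments: list[np.ndarray]  # per run: fold index of each subject


def make_cv_plan(labels, k: int, runs: int, seed: int) -> CVPlan:
    """Stratified fold assignments for each run (distinct derived seeds)."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smaller class size {counts.min()}")
    run_seeds = np.random.SeedSequence(seed).generate_state(runs) % (2 ** 31 - 1)
    assignments = []
    for rs in run_seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rs))
        folds = np.empty(len(y), dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            folds[test_idx] = f
        assignments.append(folds)
    return CVPlan(k, runs, seed, assignments)


@dataclass
class PipelineConfig:
    """Switchable variants of the classification pipeline."""

    transform: str = "dtcwt"  # or "dwt"
    scale: int | None = None  # None -> scale with 16x16 subbands
    n_components: int = 20
    use_lda: bool = True
    C1: float = 1.0
    C2: float = 1.0
    epsilon: float = 1e-6
    k: int = 5
    runs: int = 10
    seed: int = 0

    @property
    def variant_label(self) -> str:
        parts = [self.transform.upper(), "PCA"]
        if self.use_lda:
            parts.append("LDA")
        parts.append("TSVM")
        return " + ".join(parts)

    def to_dict(self) -> dict:
        return {
            "transform": self.transform, "scale": self.scale,
            "n_components": self.n_components, "use_lda": self.use_lda,
            "C1": self.C1, "C2": self.C2, "epsilon": self.epsilon,
            "k": self.k, "runs": self.runs, "seed": self.seed,
        }


@dataclass
class MetricsReport:
    """mean +- sd of each statistic over runs, plus the run x fold table."""

    summary: dict[str, tuple[float, float]]
    fold_accuracy: pd.DataFrame  # rows = folds, columns = runs (fractions)
    per_run: list[dict[str, float]]
    variant: str
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return self.summary["accuracy"][0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "config": self.config,
                "summary": {
                    name: {"mean": m, "sd": s} for name, (m, s) in self.summary.items()
                },
            },
            indent=2,
            allow_nan=True,
        )

    def save(self, prefix) -> None:
        """Write <prefix>_folds.tsv (run x fold accuracies) and <prefix>_summary.json."""
        self.fold_accuracy.to_csv(f"{prefix}_folds.tsv", sep="\t")
        with open(f"{prefix}_summary.json", "w") as fh:
            fh.write(self.to_json())


def fit_pipeline_fold(Xtr, ytr, config: PipelineConfig):
    """Fit PCA (-> LDA) -> TSVM on training data; returns a predict closure."""
    bound = max_components(len(ytr), Xtr.shape[1])
    pca = pca_fit(Xtr, min(config.n_components, bound))
    Ztr = pca_transform(pca, Xtr)
    lda = None
    if config.use_lda:
        lda = lda_fit(Ztr, ytr)
        Ztr = lda_transform(lda, Ztr).F
    model = tsvm_fit(
        TSVMProblem(Ztr[ytr == 1], Ztr[ytr == -1],
                    C1=config.C1, C2=config.C2, epsilon=config.epsilon)
    )

    def predict(Xte):
        Z = pca_transform(pca, Xte)
        if lda is not None:
            Z = lda_transform(lda, Z).F
        return tsvm_predict(model, Z)

    return predict, (pca, lda, model)


def run_pipeline_cv(cohort, config: PipelineConfig | None = None) -> MetricsReport:
    """Repeated stratified k-fold CV of the full pipeline.

    ``cohort`` is either a list of :class:`SubjectStack` (features are
    extracted once, deterministically) or a prebuilt :class:`FeatureMatrix`.
    """
    config = config or PipelineConfig()
    if isinstance(cohort, FeatureMatrix):
        fm = cohort
    else:
        fm = build_feature_matrix(list(cohort), transform=config.transform,
                                  scale=config.scale)
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("cohort must contain both classes")

    plan = make_cv_plan(fm.labels, config.k, config.runs, config.seed)
    fold_acc = np.full((config.k, config.runs), np.nan)
    per_run: list[dict[str, float]] = []
    for r, folds in enumerate(plan.fold_assignments):
        pooled = ConfusionMatrix()
        for f in range(config.k):
            te = folds == f
            tr = ~te
            predict, _ = fit_pipeline_fold(fm.X[tr], fm.labels[tr], config)
            cm = ConfusionMatrix.from_labels(fm.labels[te], predict(fm.X[te]))
            pooled = pooled + cm
            fold_acc[f, r] = compute_metrics(cm)["accuracy"]
        metrics = compute_metrics(pooled)
        for name, val in metrics.items():
            if not np.isfinite(val):
                log.warning("run %d: metric %s undefined (empty class)", r, name)
        per_run.append(metrics)

    summary = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per_run], dtype=float)
        ok = np.isfinite(vals)
        summary[name] = (
            (float(np.mean(vals[ok])), float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan)
            if ok.any()
            else (np.nan, np.nan)
        )

    table = pd.DataFrame(
        fold_acc,
        index=[f"fold_{i + 1}" for i in range(config.k)],
        columns=[f"run_{j + 1}" for j in range(config.runs)],
    )
    return MetricsReport(summary, table, per_run, config.variant_label, config.to_dict())
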