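"""Hierarchical three-task evaluation protocol.

Three sequential binary tasks are evaluated independently:

1. ``invasive_vs_noninvasive`` — all diagnoses, positive = invasive;
2. ``preinvasive_vs_benign`` — benign/atypia/dcis, positive = atypia+dcis;
3. ``dcis_vs_atypia`` — atypia/dcis, positive = dcis.

Each task runs leave-one-out cross-validation with a degree-3
polynomial-kernel SVM.  The training fold of every split is balanced by
subsampling the majority class down to the minority size (so chance is
50%), features are standardized on the training fold, and when the
training-sample count is smaller than the feature count the fold is
projected onto the first 20 principal components (PCA fit on the
training fold only).  The whole procedure is repeated ``n_repeats``
times (default 100) with per-repeat seeds ``base_seed + r`` and the
per-repeat accuracy/sensitivity/specificity are averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .label_model import DIAGNOSES, ValidationError

__all__ = [
    "TaskSpec",
    "TASKS",
    "EvalConfig",
    "TaskDataset",
    "EvalResult",
    "TaskModel",
    "make_task_dataset",
    "balanced_subsample",
    "compute_metrics",
    "loo_evaluate",
    "fit_task_model",
    "hierarchical_predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskSpec:
    name: str
    include_filter: frozenset[str]
    positive_classes: frozenset[str]


TASKS: dict[str, TaskSpec] = {
    "invasive_vs_noninvasive": TaskSpec(
        "invasive_vs_noninvasive",
        include_filter=frozenset(DIAGNOSES),
        positive_classes=frozenset({"invasive"}),
    ),
    "preinvasive_vs_benign": TaskSpec(
        "preinvasive_vs_benign",
        include_filter=frozenset({"benign", "atypia", "dcis"}),
        positive_classes=frozenset({"atypia", "dcis"}),
    ),
    "dcis_vs_atypia": TaskSpec(
        "dcis_vs_atypia",
        include_filter=frozenset({"atypia", "dcis"}),
        positive_classes=frozenset({"dcis"}),
    ),
}


@dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 100
    pca_components: int = 20
    svm_degree: int = 3
    svm_cost: float = 1.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValidationError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.pca_components < 1:
            raise ValidationError(
                f"pca_components must be >= 1, got {self.pca_components}"
            )


@dataclass(frozen=True)
class TaskDataset:
    task: TaskSpec
    X: np.ndarray  # (n, d)
    y: np.ndarray  # (n,) in {0, 1}; 1 = positive class
    ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class EvalResult:
    """Per-repeat metrics plus their means and pooled-contingency ratios."""

    task_name: str
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_repeats(self) -> int:
        return len(self.accuracy)

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def pooled(self) -> dict[str, float]:
        """Metrics computed from contingencies summed across repeats."""
        tp, tn = int(self.tp.sum()), int(self.tn.sum())
        fp, fn = int(self.fp.sum()), int(self.fn.sum())
        total = tp + tn + fp + fn
        return {
            "accuracy": (tp + tn) / total if total else float("nan"),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }

    def to_dict(self) -> dict:
        return {
            "task": self.task_name,
            "n_repeats": self.n_repeats,
            "mean": {
                "accuracy": self.mean_accuracy,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
            },
            "pooled": self.pooled,
            "per_repeat": {
                "accuracy": self.accuracy.tolist(),
                "sensitivity": self.sensitivity.tolist(),
                "specificity": self.specificity.tolist(),
                "tp": self.tp.tolist(),
                "tn": self.tn.tolist(),
                "fp": self.fp.tolist(),
                "fn": self.fn.tolist(),
            },
        }


def make_task_dataset(
    samples: list[tuple[np.ndarray, str]],
    task: TaskSpec,
    ids: list[str] | None = None,
) -> TaskDataset:
    """Filter samples by the task's include set and binarize diagnoses."""
    for _, diag in samples:
        if diag not in DIAGNOSES:
            raise ValidationError(f"unknown diagnosis {diag!r}")
    if ids is None:
        ids = [str(i) for i in range(len(samples))]
    kept = [
        (np.asarray(x, dtype=float), diag, sid)
        for (x, diag), sid in zip(samples, ids)
        if diag in task.include_filter
    ]
    if not kept:
        raise ValidationError(f"task {task.name}: no samples after filtering")
    lengths = {len(x) for x, _, _ in kept}
    if len(lengths) != 1:
        raise ValidationError(f"feature vectors have unequal lengths: {sorted(lengths)}")
    X = np.stack([x for x, _, _ in kept])
    y = np.array([1 if d in task.positive_classes else 0 for _, d, _ in kept])
    for cls in (0, 1):
        if int((y == cls).sum()) < 2:
            raise ValidationError(
                f"task {task.name}: needs >= 2 samples per class, "
                f"got {int((y == 1).sum())} positive / {int((y == 0).sum())} negative"
            )
    return TaskDataset(task=task, X=X, y=y, ids=tuple(s for _, _, s in kept))


def balanced_subsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample of *y*, shuffled.

    Each class is downsampled without replacement to the minority-class
    size.  Deterministic given the generator state.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    n_min = min(int((y == c).sum()) for c in classes)
    chosen: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        chosen.append(rng.choice(idx, size=n_min, replace=False))
    out = np.concatenate(chosen)
    rng.shuffle(out)
    return out


def compute_metrics(
    predictions: np.ndarray, truths: np.ndarray, positive_label: int = 1
) -> tuple[float, float, float, int, int, int, int]:
    """(accuracy, sensitivity, specificity, TP, TN, FP, FN).

    accuracy = (TP+TN)/(TP+TN+FP+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  Ratios with zero denominators come back
    as NaN with a logged warning.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValidationError(
            f"prediction/truth length mismatch: {predictions.shape} vs {truths.shape}"
        )
    pos_p = predictions == positive_label
    pos_t = truths == positive_label
    tp = int((pos_p & pos_t).sum())
    tn = int((~pos_p & ~pos_t).sum())
    fp = int((pos_p & ~pos_t).sum())
    fn = int((~pos_p & pos_t).sum())
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else float("nan")
    if tp + fn:
        sensitivity = tp / (tp + fn)
    else:
        logger.warning("sensitivity undefined: no positive truths")
        sensitivity = float("nan")
    if tn + fp:
        specificity = tn / (tn + fp)
    else:
        logger.warning("specificity undefined: no negative truths")
        specificity = float("nan")
    return accuracy, sensitivity, specificity, tp, tn, fp, fn


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    return mu, sigma


def _pca_fit(X: np.ndarray, n_components: int) -> np.ndarray:
    """Principal axes (rows) of centered *X*; X is already standardized."""
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return vt[: min(n_components, vt.shape[0])]


@dataclass(frozen=True)
class TaskModel:
    """A classifier fitted on one (subsampled, standardized, optionally
    PCA-projected) training set, bundling its preprocessing."""

    task_name: str
    svm: SVC
    mu: np.ndarray
    sigma: np.ndarray
    components: np.ndarray | None  # (k, d) or None when PCA was skipped

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mu) / self.sigma
        if self.components is not None:
            Z = Z @ self.components.T
        return self.svm.predict(Z)


def _fit_one(
    X_train: np.ndarray, y_train: np.ndarray, config: EvalConfig, task_name: str = ""
) -> TaskModel:
    mu, sigma = _standardize_fit(X_train)
    Z = (X_train - mu) / sigma
    components = None
    # n == d still leaves the fold underdetermined (the polynomial kernel
    # matrix is near-diagonal and the fit memorizes), so reduce at <= d
    if len(Z) <= Z.shape[1]:
        components = _pca_fit(Z, config.pca_components)
        Z = Z @ components.T
    svm = SVC(
        kernel="poly",
        degree=config.svm_degree,
        C=config.svm_cost,
        gamma="auto",  # kernel scale 1/n_features
        coef0=0.0,
    )
    svm.fit(Z, y_train)
    return TaskModel(
        task_name=task_name, svm=svm, mu=mu, sigma=sigma, components=components
    )


_MAX_RESUBSAMPLE = 10


def loo_evaluate(dataset: TaskDataset, config: EvalConfig) -> EvalResult:
    """Leave-one-out evaluation with balanced training-fold subsampling.

    Every original sample is tested exactly once per repeat; repeat *r*
    uses seed ``base_seed + r``.  Fully deterministic given the config.
    """
    X, y = dataset.X, dataset.y
    n = len(y)
    for cls in (0, 1):
        if int((y == cls).sum()) < 2:
            raise ValidationError("loo_evaluate needs >= 2 samples per class")

    acc = np.empty(config.n_repeats)
    sens = np.empty(config.n_repeats)
    spec = np.empty(config.n_repeats)
    tps = np.empty(config.n_repeats, dtype=int)
    tns = np.empty(config.n_repeats, dtype=int)
    fps = np.empty(config.n_repeats, dtype=int)
    fns = np.empty(config.n_repeats, dtype=int)

    for r in range(config.n_repeats):
        rng = np.random.default_rng(config.base_seed + r)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            train_idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            y_train_full = y[train_idx]
            sub = balanced_subsample(y_train_full, rng)
            tries = 0
            while len(np.unique(y_train_full[sub])) < 2 and tries < _MAX_RESUBSAMPLE:
                logger.warning(
                    "degenerate training fold (split %d, repeat %d); re-subsampling",
                    i,
                    r,
                )
                sub = balanced_subsample(y_train_full, rng)
                tries += 1
            chosen = train_idx[sub]
            if len(np.unique(y[chosen])) < 2:
                # unfixable (a class vanished from the fold entirely):
                # predict the fold's majority class
                preds[i] = int(np.bincount(y[chosen]).argmax())
                continue
            model = _fit_one(X[chosen], y[chosen], config, dataset.task.name)
            preds[i] = int(model.predict(X[i : i + 1])[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, s, p, tp, tn, fp, fn = compute_metrics(preds, y)
        acc[r], sens[r], spec[r] = a, s, p
        tps[r], tns[r], fps[r], fns[r] = tp, tn, fp, fn

    return EvalResult(
        task_name=dataset.task.name,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        tp=tps,
        tn=tns,
        fp=fps,
        fn=fns,
    )


def fit_task_model(dataset: TaskDataset, config: EvalConfig) -> TaskModel:
    """Fit one model on the full (balanced-subsampled) task dataset, for
    use in the hierarchical cascade."""
    rng = np.random.default_rng(config.base_seed)
    sub = balanced_subsample(dataset.y, rng)
    return _fit_one(dataset.X[sub], dataset.y[sub], config, dataset.task.name)


def hierarchical_predict(
    features: np.ndarray, models: dict[str, TaskModel]
) -> str:
    """Cascade inference: task-1 positive -> invasive; else task-2
    negative -> benign; else task-3 decides dcis vs atypia."""
    for name in TASKS:
        if name not in models:
            raise ValidationError(f"missing trained model for task {name!r}")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if models["invasive_vs_noninvasive"].predict(x)[0] == 1:
        return "invasive"
    if models["preinvasive_vs_benign"].predict(x)[0] == 0:
        return "benign"
    return "dcis" if models["dcis_vs_atypia"].predict(x)[0] == 1 else "atypia"
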