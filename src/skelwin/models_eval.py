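"""Classifier training/evaluation protocols and the classification metric suite.

Two tasks are supported: binary fall detection (the five fall classes
collapsed to the positive class) and 12-class activity recognition.  The
evaluation protocol is Monte-Carlo cross-validation: ``rounds`` repeated
random 70/30 train/test splits of the pooled windows, each round fitting a
fresh classifier, with metrics reported as mean +- sd over rounds.

Metrics are computed from the confusion counts:

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

expressed as percentages; a zero-denominator ratio is reported as 0 with a
warning.  Multiclass metrics are the global accuracy plus unweighted (macro)
means of the per-class one-vs-rest values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from skelwin.windowing import FeatureMatrix

logger = logging.getLogger(__name__)

#: activity ids 1-5 are fall classes; 6-12 are daily activities
FALL_IDS = frozenset(range(1, 6))
VOCABULARY = tuple(range(1, 13))

#: binary task encoding
FALL, NOT_FALL = 1, 0

MODEL_IDS = ("rf", "svm", "mlp", "knn", "adaboost")
METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


def collapse_to_binary(labels: Sequence[int]) -> np.ndarray:
    """Map activity ids 1-5 to fall (1) and 6-12 to not-fall (0)."""
    arr = np.asarray(labels, dtype=int)
    if arr.size and (arr.min() < 1 or arr.max() > 12):
        bad = arr[(arr < 1) | (arr > 12)]
        raise ValueError(f"labels outside the 1-12 vocabulary: {np.unique(bad).tolist()}")
    return np.where(arr <= 5, FALL, NOT_FALL)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with a declared positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true, pred, positive) -> ConfusionCounts:
    """Count TP/FP/TN/FN of ``pred`` against ``true`` for the positive class."""
    t = np.asarray(true)
    p = np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


@dataclass(frozen=True)
class Metrics:
    """One evaluation round's metric values, as percentages in [0, 100]."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reported as 0", name)
        return 0.0
    return 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Evaluate the five metric formulas on one confusion table."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        logger.warning("F1 undefined (precision + recall = 0); reported as 0")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return Metrics(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=f1,
    )


def multiclass_metrics(
    true, pred, vocabulary: Optional[Sequence[int]] = None
) -> Metrics:
    """Global accuracy plus macro one-vs-rest precision/recall/specificity/F1.

    Classes absent from the truth vector are excluded from the macro means
    with a warning.
    """
    t = np.asarray(true)
    p = np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty label vectors")
    classes = np.unique(t) if vocabulary is None else np.asarray(sorted(vocabulary))
    per_class: list[Metrics] = []
    for c in classes:
        if not np.any(t == c):
            logger.warning("class %s absent from truth; excluded from macro means", c)
            continue
        per_class.append(compute_metrics(confusion(t, p, positive=c)))
    accuracy = 100.0 * float(np.mean(t == p))
    macro = lambda name: float(np.mean([getattr(m, name) for m in per_class]))
    return Metrics(
        accuracy=accuracy,
        precision=macro("precision"),
        recall=macro("recall"),
        specificity=macro("specificity"),
        f1=macro("f1"),
    )


def confusion_matrix_table(true, pred, classes: Sequence[int]) -> np.ndarray:
    """Square confusion matrix: rows = true class, columns = predicted."""
    t = np.asarray(true)
    p = np.asarray(pred)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        mat[idx[int(ti)], idx[int(pi)]] += 1
    return mat


@dataclass(frozen=True)
class ProtocolConfig:
    """Evaluation protocol: which model, how many rounds, split fraction, seed."""

    model: str = "rf"
    rounds: int = 10
    train_fraction: float = 0.70
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_IDS}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def make_model(model_id: str, seed: int = 0, standardize: bool = False):
    """Instantiate a classifier at library-default hyperparameters.

    Only the random seeds of the stochastic models are pinned; all other
    hyperparameters are scikit-learn defaults.
    """
    if model_id == "rf":
        model = RandomForestClassifier(random_state=seed)
    elif model_id == "svm":
        model = SVC(random_state=seed)
    elif model_id == "mlp":
        model = MLPClassifier(random_state=seed)
    elif model_id == "knn":
        model = KNeighborsClassifier()
    elif model_id == "adaboost":
        model = AdaBoostClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown model {model_id!r}; choose from {MODEL_IDS}")
    if standardize:
        logger.info("feature standardization active for model %s", model_id)
        return make_pipeline(StandardScaler(), model)
    return model


@dataclass
class MetricsReport:
    """Per-round metrics with mean +- sd, plus per-round confusion matrices."""

    task: str
    model: str
    rounds: list[Metrics]
    confusions: list[np.ndarray] = field(default_factory=list)
    classes: tuple = ()

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.rounds]))

    def sd(self, name: str) -> float:
        return float(np.std([getattr(m, name) for m in self.rounds], ddof=1)) if len(
            self.rounds
        ) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            name: {"mean": self.mean(name), "sd": self.sd(name)}
            for name in METRIC_NAMES
        }

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "model": self.model,
            "n_rounds": len(self.rounds),
            "metrics": self.summary(),
            "per_round": [m.as_dict() for m in self.rounds],
        }


_MAX_REDRAWS = 100


def _split_with_all_classes(
    y: np.ndarray,
    train_fraction: float,
    seed: int,
    rounds: int,
    groups: Optional[np.ndarray] = None,
):
    """70/30 split; if the training part misses a class, redraw with a new seed.

    With ``groups`` (e.g. video ids per window), whole groups go to one side
    of the split, preventing overlapping windows of the same video from
    leaking between train and test.
    """
    n = len(y)
    idx = np.arange(n)
    n_classes = len(np.unique(y))
    attempt_seed = seed
    for _ in range(_MAX_REDRAWS):
        state = attempt_seed % (2**31 - 1)
        if groups is None:
            tr, te = train_test_split(idx, train_size=train_fraction, random_state=state)
        else:
            splitter = GroupShuffleSplit(
                n_splits=1, train_size=train_fraction, random_state=state
            )
            tr, te = next(splitter.split(idx, y, groups))
        if len(np.unique(y[tr])) == n_classes:
            return tr, te
        logger.warning(
            "training split (seed %d) missing a class; redrawing", attempt_seed
        )
        # jump past the per-round seeds so redraws never collide with them
        attempt_seed += rounds
    raise RuntimeError("could not draw a training split containing every class")


def run_protocol(
    matrix: FeatureMatrix,
    config: ProtocolConfig,
    task: str = "multiclass",
    groups: Optional[Sequence] = None,
) -> MetricsReport:
    """Repeated random-split evaluation of one classifier on one feature matrix.

    For round r the split uses seed ``config.seed + r``; the model is fitted
    on the training rows and metrics computed on the test rows.  ``task`` is
    ``"binary"`` (labels collapsed to fall / not-fall, recall measured on the
    fall class) or ``"multiclass"`` (macro averaging over the vocabulary).
    Passing per-row ``groups`` (video ids) switches to split-by-video: whole
    videos are assigned to one side, for honest generalization estimates.
    """
    if task not in ("binary", "multiclass"):
        raise ValueError(f"unknown task {task!r}")
    y = collapse_to_binary(matrix.labels) if task == "binary" else matrix.labels.copy()
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise ValueError(f"{task} evaluation needs at least 2 classes, got {classes}")
    X = matrix.values
    group_arr = None if groups is None else np.asarray(groups)
    if group_arr is not None and group_arr.shape != (matrix.n_windows,):
        raise ValueError("groups must supply one id per window")
    rounds: list[Metrics] = []
    confusions: list[np.ndarray] = []
    for r in range(config.rounds):
        tr, te = _split_with_all_classes(
            y, config.train_fraction, config.seed + r, config.rounds, groups=group_arr
        )
        model = make_model(config.model, seed=config.seed + r, standardize=config.standardize)
        model.fit(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]))
        if task == "binary":
            rounds.append(compute_metrics(confusion(y[te], pred, positive=FALL)))
        else:
            rounds.append(multiclass_metrics(y[te], pred))
        confusions.append(confusion_matrix_table(y[te], pred, classes))
    return MetricsReport(
        task=task, model=config.model, rounds=rounds, confusions=confusions, classes=classes
    )
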