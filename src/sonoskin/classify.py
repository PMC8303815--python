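"""SVM classification with stratified ten-fold cross-validation.

Six tasks are evaluated, each in a binary and a multiclass flavour:
``Nevus vs. others``, ``MM vs. others``, ``BCC vs. others``,
``Nevus vs. BCC``, ``Nevus vs. MM``, ``BCC vs. MM``.  Pairwise binary tasks
train and test on the two named classes only; one-vs-others binary tasks
relabel all samples; multiclass tasks always train on the three-way labels,
and a pairwise multiclass task is scored only on samples of its two named
classes (a third-class prediction counts as an error).

The classifier is a linear soft-margin SVM (C = 1, class-balanced weights),
with per-fold feature standardization and median imputation of undefined
(NaN) features, both computed on the training fold only.  A linear kernel is
required for the SVM-weight-based feature ranking to be meaningful.

Accuracy, sensitivity and specificity are fold means; the ROC curve and its
AUC are computed from the pooled out-of-fold decision scores, with the AUC
equal to the Mann-Whitney concordance probability (ties counted half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import EvaluationError

TASKS = ("Nevus vs. others", "MM vs. others", "BCC vs. others",
         "Nevus vs. BCC", "Nevus vs. MM", "BCC vs. MM")
MODES = ("binary", "multiclass")

_CANON = {"nevus": "nevus", "bcc": "BCC", "mm": "MM"}


@dataclass(frozen=True)
class TaskSpec:
    """One classification task (which classes, against what)."""

    task: str
    mode: str = "binary"

    def __post_init__(self):
        if self.task not in TASKS:
            raise EvaluationError(f"unknown task {self.task!r}")
        if self.mode not in MODES:
            raise EvaluationError(f"unknown mode {self.mode!r}")

    @property
    def positive(self) -> str:
        return _CANON[self.task.split(" vs. ")[0].lower()]

    @property
    def versus(self) -> str | None:
        """The single negative class of a pairwise task, else None."""
        other = self.task.split(" vs. ")[1]
        return None if other == "others" else _CANON[other.lower()]


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign samples to ``k`` groups with per-class counts equal up to 1.

    Each class's samples are shuffled with the seeded generator and dealt
    round-robin, so class ratios are preserved across groups (e.g. 110/130/70
    samples split into 10 groups of exactly 11/13/7).  Deterministic per seed.
    """
    labels = np.asarray(labels)
    if k < 1:
        raise EvaluationError("fold count must be >= 1")
    rng = np.random.default_rng(seed)
    groups = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < k:
            raise EvaluationError(
                f"class {cls!r} has {len(idx)} samples, fewer than {k} folds")
        idx = rng.permutation(idx)
        groups[idx] = np.arange(len(idx)) % k
    return groups


def task_labeling(labels, spec: TaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Select the samples a task uses and produce its training labels.

    Returns ``(indices, task_labels)``.  Binary task labels are 1 for the
    positive (first-named) class and 0 otherwise; multiclass labels keep the
    three-way class strings for all samples.
    """
    labels = np.asarray(labels)
    present = set(labels)
    needed = {spec.positive} | ({spec.versus} if spec.versus else set())
    missing = needed - present
    if missing:
        raise EvaluationError(f"task {spec.task!r} requires absent class(es) "
                              f"{sorted(missing)}")
    if spec.mode == "multiclass":
        return np.arange(len(labels)), labels.copy()
    if spec.versus is None:
        idx = np.arange(len(labels))
    else:
        idx = np.nonzero((labels == spec.positive) | (labels == spec.versus))[0]
    return idx, (labels[idx] == spec.positive).astype(int)


@dataclass
class SVMModel:
    """A fitted linear SVM with its preprocessing state.

    Stores the training-fold imputation medians and standardization
    statistics so prediction applies the identical transform.  In
    multiclass mode one one-vs-rest SVC is kept per class; decision-score
    ties break toward the class with the larger training prevalence.
    """

    mode: str
    medians: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    classes: list
    estimators: list = field(default_factory=list)
    prevalence: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.take(self.medians, np.nonzero(nan)[1])
        return (X - self.mean) / self.std

    @property
    def coef(self) -> np.ndarray:
        """Linear weights in standardized feature space (binary model)."""
        return self.estimators[0].coef_.ravel()


def train_svm(X, y, mode: str = "binary", C: float = 1.0) -> SVMModel:
    """Fit a linear soft-margin SVM with balanced class weights.

    NaN features are imputed with the training-set median; features are then
    standardized with the training mean/std.  Binary positive class is the
    label 1 (or the lexicographically larger of two labels); multiclass
    fits one-vs-rest machines.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise EvaluationError("training set contains a single class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        medians = np.nanmedian(X, axis=0)
    if np.isnan(medians).any():
        raise EvaluationError("a feature column is entirely missing")
    Xi = X.copy()
    nan = np.isnan(Xi)
    if nan.any():
        Xi[nan] = np.take(medians, np.nonzero(nan)[1])
    mean = Xi.mean(axis=0)
    std = Xi.std(axis=0)
    std[std == 0] = 1.0
    Xs = (Xi - mean) / std

    model = SVMModel(mode=mode, medians=medians, mean=mean, std=std,
                     classes=classes)
    if mode == "binary":
        est = SVC(kernel="linear", C=C, class_weight="balanced")
        est.fit(Xs, y)
        model.estimators = [est]
    elif mode == "multiclass":
        model.prevalence = np.array([(y == c).sum() for c in classes], dtype=float)
        for c in classes:
            est = SVC(kernel="linear", C=C, class_weight="balanced")
            est.fit(Xs, (y == c).astype(int))
            model.estimators.append(est)
    else:
        raise EvaluationError(f"unknown mode {mode!r}")
    return model


def predict(model: SVMModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and decision scores for a batch.

    Binary: the score is the signed distance to the separating hyperplane
    for the positive class; a score of exactly 0 predicts the negative
    class.  Multiclass: scores are the per-class one-vs-rest decision
    values; the label is the argmax, ties broken by training prevalence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.medians):
        raise EvaluationError("feature dimension does not match the model")
    Xs = model.transform(X)
    if model.mode == "binary":
        scores = model.estimators[0].decision_function(Xs)
        neg, pos = model.classes[0], model.classes[-1]
        labels = np.where(scores > 0, pos, neg)
        return labels, scores
    scores = np.column_stack([est.decision_function(Xs)
                              for est in model.estimators])
    # argmax with prevalence tie-break: perturb by a prevalence-ordered
    # epsilon ranking (never changes a strict argmax)
    order = np.argsort(np.argsort(model.prevalence))
    keyed = scores + 1e-12 * order
    labels = np.asarray(model.classes, dtype=object)[np.argmax(keyed, axis=1)]
    return labels, scores


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise EvaluationError("empty confusion table")


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(Sens, Spec, ACC) = (TP/(TP+FN), TN/(TN+FP), (TP+TN)/total).

    An empty positive or negative margin yields NaN for the affected rate.
    """
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else np.nan
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else np.nan
    acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    return sens, spec, acc


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and AUC from decision scores.

    All score thresholds are swept (tied scores grouped), giving points
    (1-Spec, Sens) from (0,0) to (1,1); the AUC is the trapezoidal integral
    and equals the Mann-Whitney concordance probability with half credit
    for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:  # always true, kept for clarity
        tpr = np.append(tpr, 1.0)
        fpr = np.append(fpr, 1.0)
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


@dataclass
class EvaluationReport:
    """Cross-validated performance of one task/mode combination."""

    task: str
    mode: str
    sens: float
    spec: float
    acc: float
    auc: float
    roc_points: np.ndarray
    per_fold: list[dict]
    seed: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "task": self.task, "mode": self.mode, "sens": self.sens,
            "spec": self.spec, "acc": self.acc, "auc": self.auc,
            "roc_points": np.asarray(self.roc_points).tolist(),
            "per_fold": self.per_fold, "seed": self.seed,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        d = dict(d)
        d["roc_points"] = np.asarray(d["roc_points"], dtype=float)
        return cls(**d)


def cross_validate(X, labels, spec: TaskSpec, folds: np.ndarray,
                   C: float = 1.0, seed: int = 0,
                   feature_subset: np.ndarray | None = None) -> EvaluationReport:
    """Ten-fold (or k-fold) cross-validation of one task.

    ``folds`` assigns every sample of the full dataset to a group; the task
    selects its own subset of samples.  Sens/Spec/ACC are means over folds;
    the ROC/AUC pools the out-of-fold decision scores of the positive class.
    ``feature_subset`` (boolean or index array over columns) supports the
    leave-one-feature-out ablation.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    if len(folds) != len(labels) or len(labels) != len(X):
        raise EvaluationError("features, labels and folds must be aligned")
    if feature_subset is not None:
        X = X[:, feature_subset]
    sel, y_task = task_labeling(labels, spec)
    sel_set = np.zeros(len(labels), dtype=bool)
    sel_set[sel] = True

    per_fold = []
    pooled_scores, pooled_truth = [], []
    for g in np.unique(folds):
        test = sel_set & (folds == g)
        train = sel_set & (folds != g)
        test_sel = np.nonzero(test)[0]
        if test_sel.size == 0:
            raise EvaluationError(f"fold {g} holds no samples of this task")
        y_map = dict(zip(sel, y_task))
        y_train = np.asarray([y_map[i] for i in np.nonzero(train)[0]])
        y_test = np.asarray([y_map[i] for i in test_sel])
        model = train_svm(X[train], y_train, mode=spec.mode, C=C)
        pred, scores = predict(model, X[test])
        if spec.mode == "binary":
            pos_truth = y_test == 1
            pos_pred = pred == 1
            neg_correct = ~pos_pred
            pos_scores = scores
        else:
            # pairwise multiclass tasks score only the two named classes;
            # predicting the third class counts as an error
            if spec.versus is not None:
                scored = (y_test == spec.positive) | (y_test == spec.versus)
                neg_correct = pred[scored] == y_test[scored]
            else:
                scored = np.ones(len(y_test), dtype=bool)
                neg_correct = pred[scored] != spec.positive
            pos_truth = y_test[scored] == spec.positive
            pos_pred = pred[scored] == spec.positive
            neg_correct = neg_correct & ~pos_pred
            pos_scores = scores[scored, model.classes.index(spec.positive)]
        tp = int((pos_truth & pos_pred).sum())
        fn = int((pos_truth & ~pos_pred).sum())
        tn = int((~pos_truth & neg_correct).sum())
        fp = int((~pos_truth & ~neg_correct).sum())
        sens, spc, acc = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        per_fold.append({"fold": int(g), "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                         "sens": sens, "spec": spc, "acc": acc})
        pooled_scores.append(pos_scores)
        pooled_truth.append(pos_truth)

    roc_points, auc = roc_auc(np.concatenate(pooled_scores),
                              np.concatenate(pooled_truth))
    return EvaluationReport(
        task=spec.task, mode=spec.mode,
        sens=float(np.nanmean([f["sens"] for f in per_fold])),
        spec=float(np.nanmean([f["spec"] for f in per_fold])),
        acc=float(np.mean([f["acc"] for f in per_fold])),
        auc=auc, roc_points=roc_points, per_fold=per_fold, seed=seed,
        n_samples=int(len(sel)))


def evaluate_all_tasks(X, labels, folds: np.ndarray, C: float = 1.0,
                       seed: int = 0) -> list[EvaluationReport]:
    """All six tasks in both binary and multiclass mode (12 reports)."""
    return [cross_validate(X, labels, TaskSpec(task, mode), folds, C=C, seed=seed)
            for task in TASKS for mode in MODES]


def ablation_study(X, labels, spec: TaskSpec, folds: np.ndarray,
                   C: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Leave-one-feature-out ablation.

    Re-runs the cross-validation once per feature with that feature removed
    and reports the resulting AUC and ACC with their deltas against the
    all-feature baseline.  Sorting the table by ``auc`` (or ``acc``)
    ascending ranks features by how much the framework degrades without
    them — the paper-style importance ranking.
    """
    X = np.asarray(X, dtype=float)
    baseline = cross_validate(X, labels, spec, folds, C=C, seed=seed)
    rows = []
    for f in range(X.shape[1]):
        keep = np.ones(X.shape[1], dtype=bool)
        keep[f] = False
        rep = cross_validate(X, labels, spec, folds, C=C, seed=seed,
                             feature_subset=keep)
        rows.append({"feature_idx": f + 1, "auc": rep.auc, "acc": rep.acc,
                     "delta_auc": rep.auc - baseline.auc,
                     "delta_acc": rep.acc - baseline.acc})
    return pd.DataFrame(rows)


def weight_rank_features(X, y, C: float = 1.0) -> np.ndarray:
    """Rank features by |standardized linear-SVM weight|, descending.

    This is the mechanism used to screen a larger candidate pool down to
    the retained feature set.  Returns 0-based column indices.  Binary
    labels only.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise EvaluationError("weight ranking requires binary labels")
    model = train_svm(X, y, mode="binary", C=C)
    return np.argsort(-np.abs(model.coef), kind="stable")
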