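"""Classifier wrappers, cross-validation and performance reporting.

Four classifier families are evaluated on fused feature matrices:
an RBF-kernel SVM, a small feedforward neural network, a random forest
and a K-nearest-neighbor rule. Leave-one-out (LOO) cross-validation is
the reference protocol: each unit (epoch, or subject) is held out once,
the classifier is refit on the remainder, and the pooled held-out
predictions feed one confusion matrix. Accuracy (Acc), sensitivity (Sn,
true-positive rate for the fatigue class) and specificity (Sp) are
reported as percentages, alongside ROC and precision-recall curves with
trapezoidal areas.

Min-max normalization, when requested, is refit inside every fold on
the training rows only, so held-out rows never influence the scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .entropy import MEASURES, ARSpec, EntropyParams
from .features import (
    FeatureMatrix,
    MinMaxNormalizer,
    NormalizationSpec,
    extract_feature_matrix,
)
from .preprocessing import EpochSet

POSITIVE_LABEL = "fatigue"

CLASSIFIER_KINDS = ("rbf_svm", "feedforward_net", "random_forest", "nearest_neighbor")
_STOCHASTIC = ("feedforward_net", "random_forest")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family plus its hyperparameters.

    Defaults follow the reference configuration: SVM penalty c = 2^-1
    and RBF width g = 2^-5; 20 hidden units for the network; 500 trees
    with 22 candidate variables per split for the forest (clipped to the
    feature count); 5 neighbors for KNN. Stochastic classifiers (net,
    forest) are refit ``n_restarts`` times with derived seeds and their
    metrics averaged.
    """

    kind: str = "rbf_svm"
    c: float = 2.0 ** -1
    g: float = 2.0 ** -5
    hidden_units: int = 20
    n_trees: int = 500
    mtry: int = 22
    k_neighbors: int = 5
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        for name in ("c", "g", "hidden_units", "n_trees", "mtry", "k_neighbors", "n_restarts"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation protocol: LOO (by epoch or subject) or stratified holdout."""

    scheme: str = "leave_one_out"
    unit: str = "epoch"
    holdout_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("leave_one_out", "holdout"):
            raise ValueError("scheme must be 'leave_one_out' or 'holdout'")
        if self.unit not in ("epoch", "subject"):
            raise ValueError("unit must be 'epoch' or 'subject'")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")


def build_estimator(spec: ClassifierSpec, n_features: int, seed: int | None = None):
    """Instantiate the scikit-learn estimator behind a ClassifierSpec."""
    seed = spec.seed if seed is None else seed
    if spec.kind == "rbf_svm":
        return SVC(C=spec.c, gamma=spec.g, kernel="rbf")
    if spec.kind == "feedforward_net":
        return MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=min(spec.mtry, n_features),
            random_state=seed,
            n_jobs=1,
        )
    return KNeighborsClassifier(n_neighbors=spec.k_neighbors)


@dataclass
class EvaluationReport:
    """Pooled cross-validated performance of one classifier."""

    classifier: str
    acc: float
    sn: float
    sp: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc: dict
    pr: dict
    hyperparameters: dict
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def confusion_metrics(
    predicted: Sequence, actual: Sequence, positive: str = POSITIVE_LABEL
) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity in percent from label sequences."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.size == 0:
        raise ValueError("empty prediction sequence")
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    tp, fp, tn, fn = _confusion_counts(predicted, actual, positive)
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, sn, sp


def _confusion_counts(predicted, actual, positive):
    pos_a = actual == positive
    pos_p = predicted == positive
    tp = int(np.sum(pos_p & pos_a))
    fp = int(np.sum(pos_p & ~pos_a))
    tn = int(np.sum(~pos_p & ~pos_a))
    fn = int(np.sum(~pos_p & pos_a))
    return tp, fp, tn, fn


def roc_pr_curves(scores, actual, positive: str = POSITIVE_LABEL) -> dict:
    """ROC and precision-recall curves with trapezoidal areas.

    ``scores`` are continuous decision values, larger meaning more
    confidence in the positive (fatigue) class. Tied scores collapse
    into a single threshold point.
    """
    scores = np.asarray(scores, dtype=float)
    actual = np.asarray(actual)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (actual == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores)
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, scores)
    order = np.argsort(recall)
    pr_auc = float(np.trapezoid(precision[order], recall[order]))
    return {
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": roc_auc},
        "pr": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "auc": pr_auc,
        },
    }


def split_train_test(fm: FeatureMatrix, spec: CVSpec = CVSpec(scheme="holdout")):
    """Stratified-by-state split (default 50/50), reproducible under seed."""
    classes, counts = np.unique(fm.labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two epochs of each class")
    idx = np.arange(fm.n_epochs)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=spec.holdout_fraction,
        stratify=fm.labels,
        random_state=spec.seed,
    )
    return fm.select_rows(np.sort(train_idx)), fm.select_rows(np.sort(test_idx))


def _positive_scores(clf, X, positive):
    """Continuous score for the positive class from any fitted estimator."""
    classes = list(clf.classes_)
    if positive not in classes:
        # training fold never saw the positive class; any constant works
        return np.zeros(len(X))
    sign = 1.0 if classes.index(positive) == 1 else -1.0
    if hasattr(clf, "decision_function"):
        return sign * np.asarray(clf.decision_function(X), dtype=float)
    proba = clf.predict_proba(X)
    return np.asarray(proba[:, classes.index(positive)], dtype=float)


def _folds(fm: FeatureMatrix, cv: CVSpec):
    n = fm.n_epochs
    if cv.scheme == "holdout":
        idx = np.arange(n)
        tr, te = train_test_split(
            idx, test_size=cv.holdout_fraction, stratify=fm.labels, random_state=cv.seed
        )
        yield np.sort(tr), np.sort(te)
    elif cv.unit == "epoch":
        idx = np.arange(n)
        for i in range(n):
            yield np.delete(idx, i), np.array([i])
    else:
        for sid in np.unique(fm.subject_ids):
            mask = fm.subject_ids == sid
            yield np.where(~mask)[0], np.where(mask)[0]


def _run_cv(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec,
    cv: CVSpec,
    normalization: NormalizationSpec | None,
    seed: int,
):
    """Pooled (actual, predicted, scores) over all held-out units."""
    y_true, y_pred, y_score = [], [], []
    for tr, te in _folds(fm, cv):
        train, test = fm.select_rows(tr), fm.select_rows(te)
        if normalization is not None:
            norm = MinMaxNormalizer(normalization).fit(train)
            train, test = norm.transform(train), norm.transform(test)
        if len(np.unique(train.labels)) < 2:
            warnings.warn("training fold missing a class; fold counted as error")
            y_true.extend(test.labels)
            wrong = np.where(test.labels == POSITIVE_LABEL, "normal", POSITIVE_LABEL)
            y_pred.extend(wrong)
            y_score.extend(np.zeros(len(te)))
            continue
        clf = build_estimator(clf_spec, fm.n_features, seed=seed)
        clf.fit(train.values, train.labels)
        y_true.extend(test.labels)
        y_pred.extend(clf.predict(test.values))
        y_score.extend(_positive_scores(clf, test.values, POSITIVE_LABEL))
    return np.asarray(y_true), np.asarray(y_pred), np.asarray(y_score, dtype=float)


def loo_cross_validate(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    unit: str = "epoch",
    normalization: NormalizationSpec | None = None,
    cv: CVSpec | None = None,
) -> EvaluationReport:
    """Cross-validate a classifier and pool held-out predictions.

    With LOO, every unit yields exactly one held-out prediction; the
    confusion matrix therefore sums to the unit count. For stochastic
    classifiers the whole CV is repeated ``n_restarts`` times with
    derived seeds and Acc/Sn/Sp are averaged (curves come from the first
    restart).
    """
    if cv is None:
        cv = CVSpec(scheme="leave_one_out", unit=unit, seed=clf_spec.seed)
    classes = np.unique(fm.labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    restarts = clf_spec.n_restarts if clf_spec.kind in _STOCHASTIC else 1
    accs, sns, sps = [], [], []
    first = None
    for k in range(restarts):
        res = _run_cv(fm, clf_spec, cv, normalization, seed=clf_spec.seed + k)
        if first is None:
            first = res
        a, s, p = confusion_metrics(res[1], res[0])
        accs.append(a)
        sns.append(s)
        sps.append(p)
    y_true, y_pred, y_score = first
    tp, fp, tn, fn = _confusion_counts(y_pred, y_true, POSITIVE_LABEL)
    curves = roc_pr_curves(y_score, y_true)
    hyper = {k: v for k, v in vars(clf_spec).items() if k != "kind"}
    return EvaluationReport(
        classifier=clf_spec.kind,
        acc=float(np.mean(accs)),
        sn=float(np.mean(sns)),
        sp=float(np.mean(sps)),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        roc=curves["roc"],
        pr=curves["pr"],
        hyperparameters=hyper,
        provenance={
            "cv_scheme": cv.scheme,
            "cv_unit": cv.unit,
            "n_units": int(len(y_true)),
            "n_restarts": restarts,
            "restart_acc": accs,
            "positive_label": POSITIVE_LABEL,
            "channels": list(fm.channels),
        },
    )


def cv_accuracy(
    fm: FeatureMatrix,
    clf_spec: ClassifierSpec,
    cv: CVSpec,
    normalization: NormalizationSpec | None = None,
) -> float:
    """Cross-validated accuracy as a fraction in [0, 1]."""
    y_true, y_pred, _ = _run_cv(fm, clf_spec, cv, normalization, seed=clf_spec.seed)
    return float(np.mean(y_true == y_pred))


def grid_search_svm(
    fm: FeatureMatrix,
    c_exponents: Sequence[int] = tuple(range(-5, 16, 2)),
    g_exponents: Sequence[int] = tuple(range(-15, 4, 2)),
    cv: CVSpec = CVSpec(),
    normalization: NormalizationSpec | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Grid search (c, g) for the RBF SVM on a log2 lattice.

    Returns the best ``(c, g)`` pair (ties broken toward the smallest c,
    then smallest g) and the full accuracy surface in percent.
    """
    if not len(c_exponents) or not len(g_exponents):
        raise ValueError("grids must be non-empty")
    rows = []
    best, best_acc = None, -1.0
    for ce in sorted(c_exponents):
        for ge in sorted(g_exponents):
            c, g = 2.0 ** ce, 2.0 ** ge
            acc = 100.0 * cv_accuracy(
                fm, ClassifierSpec(kind="rbf_svm", c=c, g=g), cv, normalization
            )
            rows.append({"c_exp": ce, "g_exp": ge, "c": c, "g": g, "accuracy_pct": acc})
            if acc > best_acc:
                best, best_acc = (c, g), acc
    return best, pd.DataFrame(rows)


def select_ar_order(
    epochs: EpochSet,
    candidate_orders: Sequence[int],
    clf_spec: ClassifierSpec = ClassifierSpec(),
    cv: CVSpec = CVSpec(),
    normalization: NormalizationSpec | None = NormalizationSpec(),
) -> tuple[int, dict[int, float]]:
    """Pick the AR order maximizing cross-validated accuracy.

    Ties break toward the smallest order. Returns (best_order,
    {order: accuracy_pct}).
    """
    if not candidate_orders:
        raise ValueError("need at least one candidate order")
    accs: dict[int, float] = {}
    for order in sorted(candidate_orders):
        fm = extract_feature_matrix(epochs, mode="ar", ar_spec=ARSpec(order=order))
        accs[order] = 100.0 * cv_accuracy(fm, clf_spec, cv, normalization)
    best = max(sorted(accs), key=lambda o: accs[o])
    return best, accs


def entropy_combination_study(
    epochs: EpochSet,
    clf_spec: ClassifierSpec = ClassifierSpec(),
    cv: CVSpec = CVSpec(),
    entropy_params: EntropyParams = EntropyParams(),
    normalization: NormalizationSpec | None = NormalizationSpec(),
) -> pd.DataFrame:
    """Cross-validated accuracy for every non-empty subset of {PE, AE, SE, FE}.

    The four-measure matrix is extracted once and columns are subset per
    combination, so each subset sees identical feature values. Returns a
    DataFrame with one row per subset (15 rows): pooled accuracy and the
    per-subject accuracy of the pooled held-out predictions.
    """
    full = extract_feature_matrix(epochs, mode="entropy_fusion", entropy_params=entropy_params)
    subjects = list(dict.fromkeys(str(s) for s in epochs.subject_ids))
    rows = []
    for k in range(1, len(MEASURES) + 1):
        for subset in combinations(MEASURES, k):
            cols = [i for i, (_, meas) in enumerate(full.feature_index) if meas in subset]
            fm = FeatureMatrix(
                values=full.values[:, cols],
                feature_index=[full.feature_index[i] for i in cols],
                labels=full.labels,
                subject_ids=full.subject_ids,
            )
            y_true, y_pred, _ = _run_cv(fm, clf_spec, cv, normalization, seed=clf_spec.seed)
            row = {
                "measures": "+".join(subset),
                "accuracy_pct": 100.0 * float(np.mean(y_true == y_pred)),
            }
            sids = fm.subject_ids.astype(str)
            # _run_cv pools folds in order; rebuild the row order it used
            pooled_sids = np.concatenate(
                [sids[te] for _, te in _folds(fm, cv)]
            )
            for sid in subjects:
                mask = pooled_sids == sid
                row[f"acc_{sid}"] = 100.0 * float(np.mean(y_true[mask] == y_pred[mask]))
            rows.append(row)
    return pd.DataFrame(rows)
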