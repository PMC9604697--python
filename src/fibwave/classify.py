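"""Outcome classification with repeated cross-validated LDA.

A linear discriminant is trained on per-patient features to separate
patients who relapse to AF ("recur", the positive class) from those who
maintain sinus rhythm ("SR").  Generalization is measured by stratified
patient-based 10-fold cross-validation repeated 100 times with reshuffled
folds; per repeat the pooled out-of-fold scores yield a ROC curve, the
trapezoidal AUC, and an operating point chosen to balance sensitivity and
specificity (the threshold maximizing min(Se, Sp)), from which Se, Sp,
Acc, PPV and NPV are read.  Metric values are averaged over repeats.

Feature subsets are chosen by greedy forward selection driven by the
cross-validated misclassification error, and competing models are compared
with the continuity-corrected asymptotic McNemar test on their predicted
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sct
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CrossValConfig",
    "OperatingPoint",
    "ClassifierReport",
    "lda_train",
    "roc_auc",
    "roc_operating_point",
    "repeated_cv",
    "forward_selection",
    "mcnemar_compare",
    "POSITIVE_LABEL",
]

#: the positive class of every metric: patients relapsing to AF
POSITIVE_LABEL = "recur"


@dataclass(frozen=True)
class CrossValConfig:
    """Protocol of the repeated stratified cross-validation."""

    k: int = 10
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if self.repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass(frozen=True)
class OperatingPoint:
    """ROC summary of one set of scores at the balanced threshold."""

    threshold: float
    se: float  #: sensitivity, %
    sp: float  #: specificity, %
    acc: float  #: accuracy, %
    auc: float  #: area under the ROC curve, [0, 1]
    ppv: float  #: positive predictive value, %
    npv: float  #: negative predictive value, %


@dataclass(frozen=True)
class ClassifierReport:
    """Averaged repeated-CV metrics plus per-repeat detail."""

    features: tuple[str, ...]
    se: float
    sp: float
    acc: float
    auc: float
    ppv: float
    npv: float
    per_repeat: pd.DataFrame = field(repr=False)
    #: per-patient mean out-of-fold score across repeats
    pooled_scores: np.ndarray = field(repr=False)
    #: per-patient majority-vote predicted label across repeats
    predicted: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, float | list[str]]:
        return {
            "features": list(self.features),
            "Se_pct": self.se,
            "Sp_pct": self.sp,
            "Acc_pct": self.acc,
            "AUC": self.auc,
            "PPV_pct": self.ppv,
            "NPV_pct": self.npv,
        }


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "biuf":
        return y.astype(int)
    return (y == POSITIVE_LABEL).astype(int)


def lda_train(features: np.ndarray, labels: Sequence) -> LinearDiscriminantAnalysis:
    """Fit an LDA scorer; higher decision scores mean "recur".

    The fit estimates one Gaussian per class with a pooled covariance and
    empirical class priors; the returned model's ``decision_function`` is
    the linear score w'x + b oriented toward the positive (recurrence)
    class.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(labels) == X.shape[1]:
        X = X.T
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    if np.min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    model = LinearDiscriminantAnalysis(solver="svd")
    model.fit(X, y)
    return model


def roc_auc(scores: np.ndarray, labels: Sequence) -> float:
    """Trapezoidal area under the ROC curve via the rank statistic.

    The average-rank (Mann-Whitney) form equals the trapezoidal area of
    the empirical ROC curve, handling tied scores as diagonal segments.
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sct.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_operating_point(scores: np.ndarray, labels: Sequence) -> OperatingPoint:
    """Metrics at the threshold giving the best Se/Sp balance.

    Every distinct score is tried as a threshold (predict "recur" when
    score >= threshold); the threshold maximizing min(Se, Sp) is chosen,
    ties resolved toward higher sensitivity.  This balance rule generally
    sacrifices some accuracy relative to the accuracy-maximizing point.
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.unique(s)
    pred = s[None, :] >= thresholds[:, None]  # (n_thr, n)
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    fn = n_pos - tp
    tn = n_neg - fp
    se = tp / n_pos
    sp = tn / n_neg
    balance = np.minimum(se, sp)
    best = np.flatnonzero(balance == balance.max())
    i = best[np.argmax(se[best])]

    with np.errstate(invalid="ignore"):
        ppv = np.divide(tp[i], tp[i] + fp[i]) if tp[i] + fp[i] else np.nan
        npv = np.divide(tn[i], tn[i] + fn[i]) if tn[i] + fn[i] else np.nan
    return OperatingPoint(
        threshold=float(thresholds[i]),
        se=100.0 * float(se[i]),
        sp=100.0 * float(sp[i]),
        acc=100.0 * float((tp[i] + tn[i]) / (n_pos + n_neg)),
        auc=roc_auc(s, y),
        ppv=100.0 * float(ppv),
        npv=100.0 * float(npv),
    )


def _stratified_oof_scores(
    X: np.ndarray, y: np.ndarray, k: int, random_state: int
) -> np.ndarray:
    """Out-of-fold LDA scores of one stratified k-fold cycle."""
    scores = np.empty(len(y), dtype=float)
    for attempt in range(5):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=random_state + 10_000 * attempt
        )
        try:
            for train, test in skf.split(X, y):
                model = lda_train(X[train], y[train])
                scores[test] = model.decision_function(X[test])
            return scores
        except ValueError:
            continue  # a fold lost a class: reshuffle and retry
    raise RuntimeError("could not form folds with both classes in training")


def repeated_cv(
    cohort: pd.DataFrame,
    feature_subset: Sequence[str],
    config: CrossValConfig = CrossValConfig(),
) -> ClassifierReport:
    """Repeated stratified patient-based k-fold evaluation of an LDA model.

    Per repeat, patients are reshuffled into stratified folds; each fold
    is scored by a model trained on the other k-1 folds, so every patient
    is validated exactly once per repeat.  The pooled out-of-fold scores
    of a repeat yield one operating point; reported metrics are means over
    repeats.  Bit-reproducible for a fixed ``config.seed``.
    """
    feature_subset = tuple(feature_subset)
    X = cohort[list(feature_subset)].to_numpy(dtype=float)
    y = _binary_labels(cohort["label"].to_numpy())
    n_minority = int(np.min(np.bincount(y)))
    if config.k > n_minority:
        raise ValueError(
            f"k={config.k} folds exceed the minority class size {n_minority}"
        )

    rows = []
    score_sum = np.zeros(len(y))
    vote_sum = np.zeros(len(y))
    for r in range(config.repeats):
        scores = _stratified_oof_scores(X, y, config.k, config.seed + r)
        op = roc_operating_point(scores, y)
        rows.append(
            {
                "repeat": r,
                "Se_pct": op.se,
                "Sp_pct": op.sp,
                "Acc_pct": op.acc,
                "AUC": op.auc,
                "PPV_pct": op.ppv,
                "NPV_pct": op.npv,
                "threshold": op.threshold,
            }
        )
        score_sum += scores
        vote_sum += scores >= op.threshold
    per_repeat = pd.DataFrame(rows)
    mean = per_repeat.mean(numeric_only=True)
    predicted = np.where(
        vote_sum * 2 >= config.repeats, POSITIVE_LABEL, "SR"
    )
    return ClassifierReport(
        features=feature_subset,
        se=float(mean["Se_pct"]),
        sp=float(mean["Sp_pct"]),
        acc=float(mean["Acc_pct"]),
        auc=float(mean["AUC"]),
        ppv=float(mean["PPV_pct"]),
        npv=float(mean["NPV_pct"]),
        per_repeat=per_repeat,
        pooled_scores=score_sum / config.repeats,
        predicted=predicted,
    )


def _cv_error(
    X: np.ndarray, y: np.ndarray, cols: list[int], k: int, random_state: int
) -> float:
    """Misclassification rate of an LDA on ``cols`` under k-fold CV."""
    scores = _stratified_oof_scores(X[:, cols], y, k, random_state)
    op = roc_operating_point(scores, y)
    pred = scores >= op.threshold
    return float(np.mean(pred != (y == 1)))


def forward_selection(
    cohort: pd.DataFrame,
    candidate_features: Sequence[str],
    config: CrossValConfig = CrossValConfig(repeats=10),
    inner_k: int = 5,
) -> tuple[list[str], dict[str, float]]:
    """Greedy forward feature selection under cross-validated error.

    Starting from an empty set, the candidate whose addition most reduces
    the stratified ``inner_k``-fold LDA misclassification error is added
    until no addition strictly decreases the error.  The procedure is
    repeated ``config.repeats`` times with reshuffled folds; returns the
    subset selected most frequently (the modal subset) and the selection
    frequency of each candidate across repeats.
    """
    candidates = list(candidate_features)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    X = cohort[candidates].to_numpy(dtype=float)
    y = _binary_labels(cohort["label"].to_numpy())

    counts: dict[str, int] = {c: 0 for c in candidates}
    subsets: dict[tuple[str, ...], int] = {}
    for r in range(config.repeats):
        rs = config.seed + 1_000 + r
        chosen: list[int] = []
        best_err = np.inf
        while len(chosen) < len(candidates):
            errs = [
                (_cv_error(X, y, chosen + [j], inner_k, rs), j)
                for j in range(len(candidates))
                if j not in chosen
            ]
            err, j = min(errs)
            if err < best_err - 1e-12:
                best_err = err
                chosen.append(j)
            else:
                break
        subset = tuple(sorted(candidates[j] for j in chosen))
        subsets[subset] = subsets.get(subset, 0) + 1
        for name in subset:
            counts[name] += 1
    frequency = {c: counts[c] / config.repeats for c in candidates}
    modal = max(subsets.items(), key=lambda kv: (kv[1], -len(kv[0])))[0]
    return list(modal), frequency


def mcnemar_compare(
    labels: Sequence, pred_a: Sequence, pred_b: Sequence
) -> tuple[float, float]:
    """Asymptotic McNemar test of two classifiers' error rates.

    With ``b`` = patients that only model A classifies correctly and
    ``c`` = patients that only model B classifies correctly, the
    continuity-corrected statistic ``(|b - c| - 1)^2 / (b + c)`` is
    referred to the chi-square distribution with one degree of freedom.
    Identical predictions give p = 1.
    """
    y = np.asarray(labels)
    a = np.asarray(pred_a)
    bb = np.asarray(pred_b)
    if not (len(y) == len(a) == len(bb)):
        raise ValueError("labels and predictions must have equal length")
    correct_a = a == y
    correct_b = bb == y
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return 0.0, 1.0
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    return float(stat), float(sct.chi2.sf(stat, df=1))
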