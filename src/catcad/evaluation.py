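"""Validation statistics: ROC/AUC with cross-validation, operating points,
severity-threshold selection and convergent-validity correlation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from catcad.cat import SeverityThresholds


@dataclass
class RocResult:
    """ROC curve with AUC and a DeLong 95% confidence interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float]
    fold_assignments: np.ndarray | None = None
    predictions: np.ndarray | None = None


class SensSpec(NamedTuple):
    sensitivity: float
    specificity: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be coded 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return y


# -- DeLong AUC variance ----------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC with the DeLong asymptotic confidence interval."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # structural components, positives
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # negatives
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def roc_result(
    scores: np.ndarray,
    labels: np.ndarray,
    fold_assignments: np.ndarray | None = None,
) -> RocResult:
    """Build an ROC curve (rank/trapezoid AUC) from scores and labels."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc, ci = delong_auc_ci(s, y)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        ci=ci,
        fold_assignments=fold_assignments,
        predictions=s,
    )


def cv_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    refit: str = "logistic",
) -> RocResult:
    """Cross-validated AUC from a single score/probability column.

    Out-of-fold predictions are pooled into one ROC. With
    ``refit='logistic'`` a logistic regression of the label on the score
    is fitted per training fold (the score-to-risk mapping is learned
    out-of-sample); ``refit='none'`` uses the scores as-is. Folds are
    stratified by label (plain folds when ``folds == n``, i.e.
    leave-one-out).
    """
    y = _check_binary(np.asarray(labels))
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("scores and labels must have equal length")
    if folds < 2 or folds > y.size:
        raise ValueError("need 2 <= folds <= n")
    if refit not in ("logistic", "none"):
        raise ValueError(f"unknown refit mode {refit!r}")
    if folds == y.size:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(y.size)
    fold_of = np.empty(y.size, dtype=int)
    for k, (tr, te) in enumerate(splitter.split(s.reshape(-1, 1), y)):
        if refit == "logistic" and np.unique(y[tr]).size == 2:
            lr = LogisticRegression(C=1000.0, max_iter=2000)
            lr.fit(s[tr].reshape(-1, 1), y[tr])
            preds[te] = lr.predict_proba(s[te].reshape(-1, 1))[:, 1]
        else:
            preds[te] = s[te]
        fold_of[te] = k
    return roc_result(preds, y, fold_assignments=fold_of)


def sens_spec(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> SensSpec:
    """Sensitivity and specificity of the rule ``score >= threshold``.

    A rate whose denominator is empty is returned as NaN (undefined), not 0.
    """
    y = np.asarray(labels).astype(int)
    if not np.isin(np.unique(y), (0, 1)).all():
        raise ValueError("labels must be coded 0/1")
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    sens = float(pred[y == 1].mean()) if n_pos else float("nan")
    spec = float((~pred[y == 0]).mean()) if n_neg else float("nan")
    return SensSpec(sens, spec)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Operationalized severity-cut policy.

    The lowest cut favours sensitivity (catch nearly every case), the
    middle cut balances both (Youden's J), the top cut favours
    specificity.
    """

    t1_min_sensitivity: float = 0.95
    t2_rule: str = "youden"
    t3_min_specificity: float = 0.93


class ThresholdPolicyError(ValueError):
    """Raised when no ascending triple satisfies the policy; carries the
    achievable (cut, sensitivity, specificity) frontier."""

    def __init__(self, message: str, frontier: pd.DataFrame):
        super().__init__(message)
        self.frontier = frontier


def operating_frontier(
    scores: Sequence[float], labels: Sequence[int]
) -> pd.DataFrame:
    """Sensitivity/specificity at every distinct candidate cut."""
    s = np.asarray(scores, dtype=float)
    cuts = np.unique(s)
    rows = [
        {"cut": float(c), **sens_spec(s, labels, c)._asdict()} for c in cuts
    ]
    return pd.DataFrame(rows)


def select_thresholds(
    scores: Sequence[float],
    labels: Sequence[int],
    policy: ThresholdPolicy | None = None,
) -> SeverityThresholds:
    """Pick three ascending severity cuts against a binary criterion.

    t1 = smallest cut with sensitivity >= ``t1_min_sensitivity``;
    t2 = cut maximizing Youden's J (smallest on ties);
    t3 = smallest cut with specificity >= ``t3_min_specificity``.
    Raises :class:`ThresholdPolicyError` (with the achievable frontier)
    when the constraints cannot produce a strictly ascending triple.
    """
    policy = policy or ThresholdPolicy()
    _check_binary(np.asarray(labels))
    frontier = operating_frontier(scores, labels)
    if len(frontier) < 3:
        raise ThresholdPolicyError(
            f"only {len(frontier)} distinct score value(s); "
            "cannot place three ascending cuts",
            frontier,
        )

    ok1 = frontier[frontier["sensitivity"] >= policy.t1_min_sensitivity]
    ok3 = frontier[frontier["specificity"] >= policy.t3_min_specificity]
    if ok1.empty or ok3.empty:
        raise ThresholdPolicyError(
            "sensitivity/specificity constraints unsatisfiable", frontier
        )
    t1 = float(ok1["cut"].min())
    j = frontier["sensitivity"] + frontier["specificity"] - 1.0
    t2 = float(frontier.loc[j.idxmax(), "cut"])
    t3 = float(ok3["cut"].min())
    if not t1 < t2 < t3:
        raise ThresholdPolicyError(
            f"policy produced a non-ascending triple ({t1}, {t2}, {t3})", frontier
        )
    return SeverityThresholds(t1=t1, t2=t2, t3=t3)


class PearsonResult(NamedTuple):
    r: float
    p: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a two-sided t-test p-value."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(xa, ya)
    return PearsonResult(float(res.statistic), float(res.pvalue))
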