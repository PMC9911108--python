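"""LOO-CV engine, classification metrics, ROC/AUC, permutation overfit test.

Leave-one-out cross-validation refits the model n times, each time
standardizing and resolving spline domains on the n-1 training subjects only
(no leakage) and scoring the held-out subject.  The overfitting test
compares the true-label LOO-CV accuracy T0 with the accuracies T_1..T_B
obtained after label permutations and reports

    p = (#{b : T_b > T0} + 1) / (B + 1)

with a strict inequality in the count, so ties between a permuted accuracy
and T0 favor significance.  A small p means the model's accuracy is real
signal, not overfitting; the permutations shuffle labels without
replacement, preserving the class balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_builder import FeatureMap
from .preprocessing import CohortTable, complete_cases
from .smooth_hinge import FitConfig, PenaltySpec, fit_penalized

__all__ = [
    "ConfusionMatrix",
    "LooCvResult",
    "OverfitTestResult",
    "loo_cv",
    "metrics",
    "roc_auc",
    "overfit_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for the +1 (positive) / -1 (negative) convention."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion matrix counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def metrics(cm: ConfusionMatrix) -> dict:
    """SN, SP, Precision, ACC and MCC from a confusion matrix.

    SN = TP/(TP+FN), SP = TN/(TN+FP), Precision = TP/(TP+FP),
    ACC = (TP+TN)/n, MCC = (TP*TN - FP*FN)/sqrt(prod of the four margins);
    any metric with a zero denominator is reported as 0 (MCC convention).
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "SN": ratio(tp, tp + fn),
        "SP": ratio(tn, tn + fp),
        "Precision": ratio(tp, tp + fp),
        "ACC": (tp + tn) / n,
        "MCC": float(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0,
    }


def roc_auc(scores, labels):
    """ROC points and AUC by the rank (Mann-Whitney) formulation; ties count 1/2.

    Returns ``(points, auc)`` where points is an (m, 2) array of (FPR, TPR)
    at descending score thresholds.  Constant scores give AUC 0.5.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == -1)
    keep = np.r_[np.diff(ss) != 0, True]  # last point per distinct threshold
    points = np.column_stack([
        np.r_[0.0, fps[keep] / n_neg],
        np.r_[0.0, tps[keep] / n_pos],
    ])
    return points, float(auc)


@dataclass(frozen=True)
class LooCvResult:
    accuracy: float
    confusion: ConfusionMatrix
    scores: np.ndarray
    subjects: tuple
    n_fits: int


def _prepare_folds(table: CohortTable, fmap: FeatureMap):
    """Per-fold standardized train designs and held-out rows.

    Standardization and spline domains depend only on the feature values, so
    the folds can be prepared once and reused across label permutations.
    Returns (folds, y, subjects) with folds[i] = (X_train, x_test).
    """
    cc = complete_cases(table, fmap.variables)
    n = cc.n_subjects
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 complete subjects")
    raw = cc.data[fmap.variables].to_numpy(dtype=float)
    y = cc.labels.to_numpy(dtype=float)
    folds = []
    idx_all = np.arange(n)
    for i in range(n):
        tr = idx_all != i
        Xtr_raw = raw[tr]
        mu = Xtr_raw.mean(axis=0)
        sd = Xtr_raw.std(axis=0)
        sd[sd == 0] = 1.0
        Ztr = (Xtr_raw - mu) / sd
        zte = (raw[i] - mu) / sd
        cols_tr, cols_te = [np.ones((n - 1, 1))], [np.ones(1)]
        for j, e in enumerate(fmap.entries):
            if e.encoding == "linear":
                cols_tr.append(Ztr[:, j:j + 1])
                cols_te.append(zte[j:j + 1])
            else:
                lo, hi = float(Ztr[:, j].min()), float(Ztr[:, j].max())
                from ._splines import bspline_basis

                cols_tr.append(bspline_basis(Ztr[:, j], lo, hi, e.order))
                cols_te.append(bspline_basis(zte[j], lo, hi, e.order)[0])
        folds.append((np.hstack(cols_tr), np.concatenate(cols_te)))
    return folds, y, tuple(cc.data.index)


def _loo_scores(folds, y, ridge_lambda, config, warm=None):
    """Decision score for each held-out subject given labels ``y``."""
    spec = PenaltySpec("ridge", ridge_lambda)
    scores = np.empty(len(folds))
    beta0 = warm
    for i, (Xtr, xte) in enumerate(folds):
        mask = np.ones(len(folds), dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if np.all(ytr == ytr[0]):
            logger.warning("loo_cv: fold %d train set is single-class; majority prediction", i)
            scores[i] = ytr[0] * 1e-9  # majority-class sign with negligible magnitude
            continue
        fit = fit_penalized(Xtr, ytr, spec, config, beta0=beta0)
        beta0 = fit.beta
        scores[i] = float(xte @ fit.beta)
    return scores


def loo_cv(
    table: CohortTable,
    fmap: FeatureMap,
    ridge_lambda: float = 1e-3,
    config: FitConfig | None = None,
) -> LooCvResult:
    """Leave-one-out cross-validation of the ridge smooth-hinge SVM.

    Exactly n fits are performed (n = complete cases on the map's
    variables); standardization and spline domains are re-estimated inside
    each fold.
    """
    config = config or FitConfig()
    folds, y, subjects = _prepare_folds(table, fmap)
    warm = _warm_start(folds, y, ridge_lambda, config)
    scores = _loo_scores(folds, y, ridge_lambda, config, warm=warm)
    pred = np.where(scores >= 0, 1.0, -1.0)
    cm = ConfusionMatrix.from_predictions(y, pred)
    return LooCvResult(
        accuracy=float(np.mean(pred == y)),
        confusion=cm,
        scores=scores,
        subjects=subjects,
        n_fits=len(folds),
    )


def _warm_start(folds, y, ridge_lambda, config):
    """Fit on the first fold's training set to warm-start every fold."""
    Xtr, _ = folds[0]
    ytr = np.delete(y, 0)
    if np.all(ytr == ytr[0]):
        return None
    fit = fit_penalized(Xtr, ytr, PenaltySpec("ridge", ridge_lambda), config)
    return fit.beta


@dataclass(frozen=True)
class OverfitTestResult:
    """True accuracy T0 vs the permutation distribution T_1..T_B."""

    t0: float
    t_perm: np.ndarray
    B: int
    p_value: float
    seed: int


def overfit_test(
    table: CohortTable,
    fmap: FeatureMap,
    B: int = 200,
    seed: int = 0,
    ridge_lambda: float = 1e-3,
    config: FitConfig | None = None,
) -> OverfitTestResult:
    """Permutation test of the null hypothesis that the model is overfitted.

    T0 and every T_b use the same estimator (LOO-CV accuracy): the permuted
    labels are refitted and cross-validated exactly like the true ones.
    Replicate seeds are pre-drawn from ``seed`` so replicates are
    independent and could run concurrently with identical results.
    """
    if B < 19:
        raise ValueError("B must be at least 19 for a meaningful p-value")
    config = config or FitConfig()
    folds, y, _ = _prepare_folds(table, fmap)
    warm = _warm_start(folds, y, ridge_lambda, config)

    def accuracy(labels):
        s = _loo_scores(folds, labels, ridge_lambda, config, warm=warm)
        return float(np.mean(np.where(s >= 0, 1.0, -1.0) == labels))

    t0 = accuracy(y)
    child_seeds = np.random.SeedSequence(seed).spawn(B)
    t_perm = np.empty(B)
    for b, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        t_perm[b] = accuracy(rng.permutation(y))
    p = (float(np.sum(t_perm > t0)) + 1.0) / (B + 1.0)
    logger.info("overfit_test: T0=%.3f, p=%.4g (B=%d)", t0, p, B)
    return OverfitTestResult(t0=t0, t_perm=t_perm, B=B, p_value=p, seed=seed)
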