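"""Logistic-regression classification of cases versus controls.

Unpenalized maximum-likelihood logistic regression is fitted by
iteratively reweighted least squares (IRLS).  Model reduction follows
backward stepwise elimination under the Akaike information criterion
(AIC = 2k - 2 lnL): at each step the term whose removal lowers AIC the
most is dropped, stopping when no removal improves it.  Validation is
leave-one-out cross-validation with the term set held fixed (selection is
not re-run per fold, so any selection bias is inherited by design — it is
documented, not hidden).  Discrimination is summarised by the ROC curve
over all score thresholds; ties contribute half, which makes the
trapezoid AUC exactly the Mann-Whitney U statistic over n1*n2 pairs.

With few samples and strong features the MLE can diverge (quasi-complete
separation); fits are flagged rather than penalized, since very large
coefficients are a meaningful outcome for near-separable serology data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogisticModel",
    "ClassifierEval",
    "fit_logistic",
    "backward_stepwise_aic",
    "loocv",
    "roc_auc",
    "evaluate_classifier",
]

_SEPARATION_COEF = 50.0  # |standardized coefficient| beyond this flags separation


@dataclass
class LogisticModel:
    terms: list  # feature names, intercept excluded
    coefficients: np.ndarray  # [intercept, terms...]
    log_likelihood: float
    aic: float
    converged: bool
    separation_flag: bool
    n_iter: int = 0

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xm = _design(X, self.terms)
        return _sigmoid(Xm @ self.coefficients)


@dataclass
class ClassifierEval:
    loocv_accuracy: float | None = None
    per_sample_probs: np.ndarray | None = None
    roc_points: np.ndarray | None = None  # (FPR, TPR) pairs
    auc: float | None = None
    degenerate_curve: bool = False
    insample_auc: float | None = None
    insample_roc_points: np.ndarray | None = field(default=None, repr=False)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _design(X, terms) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        Xm = X[list(terms)].to_numpy(float) if terms else np.empty((len(X), 0))
    else:
        Xm = np.asarray(X, float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
    return np.column_stack([np.ones(Xm.shape[0]), Xm])


def _feature_names(X, terms=None) -> list:
    if terms is not None:
        return list(terms)
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    arr = np.asarray(X)
    ncol = 1 if arr.ndim == 1 else arr.shape[1]
    return [f"x{j}" for j in range(ncol)]


def fit_logistic(
    X,
    y,
    terms: list | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by IRLS with an intercept.

    ``y`` is binary (0/1 or case/control labels).  Convergence is a
    max-absolute coefficient change below ``tol``.  Singular weighted
    normal equations trigger a 1e-8 ridge-jitter refit with a warning.
    Separation is flagged when a standardized coefficient exceeds 50 in
    magnitude or the likelihood keeps climbing without convergence.
    """
    y = _binary_labels(y)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    terms = _feature_names(X, terms)
    Xm = _design(X, terms) if isinstance(X, pd.DataFrame) else _design(X, None)
    if Xm.shape[1] - 1 != len(terms):
        raise ValueError("terms do not match the design matrix")
    n, k = Xm.shape
    if n < 2:
        raise ValueError("need at least 2 samples")

    beta = np.zeros(k)
    converged = False
    n_iter = 0
    jitter = ridge
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        p = np.clip(_sigmoid(eta), 1e-12, 1.0 - 1e-12)
        w = p * (1.0 - p)
        z = eta + (y - p) / w
        A = Xm.T @ (Xm * w[:, None])
        if jitter:
            A = A + jitter * np.eye(k)
        b = Xm.T @ (w * z)
        try:
            new_beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            if jitter == 0.0:
                warnings.warn("singular IRLS system; refitting with 1e-8 ridge jitter")
                jitter = 1e-8
                continue
            raise
        step = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        n_iter = it
        if step < tol:
            converged = True
            break

    eta = Xm @ beta
    p = np.clip(_sigmoid(eta), 1e-15, 1.0 - 1e-15)
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    aic = 2.0 * k - 2.0 * ll

    scale = Xm[:, 1:].std(axis=0, ddof=1) if k > 1 else np.array([])
    std_coef = beta[1:] * np.where(scale > 0, scale, 1.0)
    separation = bool((np.abs(std_coef) > _SEPARATION_COEF).any()) or (
        not converged and ll > -1e-8 * n
    )
    return LogisticModel(
        terms=terms,
        coefficients=beta,
        log_likelihood=ll,
        aic=aic,
        converged=converged,
        separation_flag=separation,
        n_iter=n_iter,
    )


def _binary_labels(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        uniq = sorted(set(arr))
        if set(uniq) <= {"case", "control"}:
            return (arr == "case").astype(float)
        if len(uniq) > 2:
            raise ValueError("labels must be binary")
        return (arr == uniq[-1]).astype(float)
    return arr.astype(float)


def backward_stepwise_aic(X: pd.DataFrame, y, terms: list | None = None) -> LogisticModel:
    """AIC backward elimination starting from the full model.

    At each step every remaining term is tentatively dropped; the drop
    with the lowest refitted AIC is kept if it beats the current model's
    AIC, ties broken by term order.  The intercept is never removed.
    """
    terms = _feature_names(X, terms)
    current = fit_logistic(X, y, terms=terms)
    while current.terms:
        best = None
        for t in current.terms:  # tie-break: first listed term wins
            reduced = [u for u in current.terms if u != t]
            cand = fit_logistic(X, y, terms=reduced)
            if best is None or cand.aic < best.aic - 1e-12:
                best = cand
        if best is not None and best.aic < current.aic:
            current = best
        else:
            break
    return current


def loocv(X: pd.DataFrame, y, terms: list) -> ClassifierEval:
    """Leave-one-out cross-validation with a fixed term set.

    Each sample's probability comes from a model refitted on the other
    n - 1 samples; accuracy thresholds the held-out probability at 0.5.
    A fold whose training data loses a class entirely falls back to an
    intercept-only prediction with a warning.
    """
    y = _binary_labels(y)
    n = len(y)
    probs = np.empty(n)
    idx_all = np.arange(n)
    Xf = X[list(terms)] if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    for i in range(n):
        tr = idx_all != i
        y_tr = y[tr]
        if len(set(y_tr)) < 2:
            warnings.warn(f"fold {i}: single-class training data; intercept-only prediction")
            probs[i] = float(y_tr.mean())
            continue
        model = fit_logistic(Xf.iloc[tr], y_tr, terms=list(Xf.columns))
        probs[i] = float(model.predict_proba(Xf.iloc[[i]])[0])
    accuracy = float(np.mean((probs > 0.5) == (y == 1.0)))
    return ClassifierEval(loocv_accuracy=accuracy, per_sample_probs=probs)


def roc_auc(scores, labels) -> ClassifierEval:
    """ROC curve over all score thresholds and its trapezoid AUC.

    Tied scores advance both coordinates at once (a diagonal segment), so
    the trapezoid area equals the Mann-Whitney statistic U / (n1 * n2)
    exactly.  Constant scores give the chance diagonal (AUC 0.5) with a
    degenerate-curve flag.
    """
    s = np.asarray(scores, float)
    y = _binary_labels(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1.0 - y_sorted)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    degenerate = len(np.unique(s)) == 1
    return ClassifierEval(roc_points=points, auc=auc, degenerate_curve=degenerate)


def evaluate_classifier(X: pd.DataFrame, y, terms: list) -> ClassifierEval:
    """LOOCV plus ROC on both held-out and in-sample probabilities.

    Which probability stream feeds a headline AUC is a reporting choice;
    both are exposed so the reader can pick either.
    """
    ev = loocv(X, y, terms)
    roc_cv = roc_auc(ev.per_sample_probs, y)
    model = fit_logistic(X, y, terms=terms)
    roc_in = roc_auc(model.predict_proba(X), y)
    return ClassifierEval(
        loocv_accuracy=ev.loocv_accuracy,
        per_sample_probs=ev.per_sample_probs,
        roc_points=roc_cv.roc_points,
        auc=roc_cv.auc,
        degenerate_curve=roc_cv.degenerate_curve,
        insample_auc=roc_in.auc,
        insample_roc_points=roc_in.roc_points,
    )
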