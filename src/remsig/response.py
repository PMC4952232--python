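"""Association and prediction-performance models for signature scores.

Firth's penalized-likelihood logistic regression links signature scores to
non-remission.  The Jeffreys-prior penalty ``l*(b) = l(b) + 0.5 log det
I(b)`` keeps estimates finite and bias-reduced even under complete
separation, which is why the odds-ratio confidence intervals can be
extremely asymmetric near separation.  Confidence intervals are profile
penalized-likelihood intervals and p values come from penalized
likelihood-ratio tests.  ROC analysis treats NON-REM as "positive", uses
the Mann–Whitney (rank) convention for the AUC, and picks the operating
threshold by maximizing Youden's J = sensitivity + specificity − 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FirthFit",
    "RocResult",
    "OptimalCutoff",
    "FirthLogisticRegression",
    "firth_logistic",
    "profile_ci",
    "roc_curve",
    "optimal_threshold",
    "auc_bootstrap_ci",
]


# ---------------------------------------------------------------- Firth core


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = p * (1.0 - p)
    info = X.T @ (w[:, None] * X)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    max_step: float = 5.0,
) -> tuple[np.ndarray, float, bool, int]:
    """Maximize the penalized log-likelihood over the ``free`` components.

    Fixed components keep their value in ``beta0`` (used by the profile
    likelihood and the penalized LRT).  Uses the hat-diagonal-modified
    score with Newton steps, component-wise step capping and step-halving.
    """
    beta = beta0.astype(float).copy()
    ll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        wsq = np.sqrt(w)
        info = X.T @ (w[:, None] * X)
        try:
            xw = wsq[:, None] * X
            h = np.einsum("ij,ij->i", xw @ np.linalg.inv(info), xw)
        except np.linalg.LinAlgError:
            break
        score = X.T @ (y - p + h * (0.5 - p))
        score_free = score[free]
        if np.max(np.abs(score_free)) < tol:
            converged = True
            break
        info_free = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(info_free, score_free)
        except np.linalg.LinAlgError:
            break
        big = np.max(np.abs(step))
        if big > max_step:
            step *= max_step / big
        new_beta = beta.copy()
        new_beta[free] += step
        new_ll = _penalized_loglik(X, y, new_beta)
        n_half = 0
        while new_ll < ll and n_half < 30:
            step *= 0.5
            new_beta = beta.copy()
            new_beta[free] += step
            new_ll = _penalized_loglik(X, y, new_beta)
            n_half += 1
        beta, ll = new_beta, new_ll
    return beta, ll, converged, it


@dataclass
class FirthFit:
    """Result of a Firth penalized logistic fit."""

    names: list[str]
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    odds_ratios: np.ndarray = field(init=False)
    conf_int: np.ndarray | None = None  # (p, 2) on OR scale
    pvalues: np.ndarray | None = None
    ci_open: np.ndarray | None = None  # (p, 2) bool: bound not bracketed

    def __post_init__(self) -> None:
        self.odds_ratios = np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"term": self.names, "coef": self.beta, "OR": self.odds_ratios})
        if self.conf_int is not None:
            out["CI_low"] = self.conf_int[:, 0]
            out["CI_high"] = self.conf_int[:, 1]
        if self.pvalues is not None:
            out["p"] = self.pvalues
        return out


def _validate_design(X: np.ndarray, names: list[str]) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name one dependent column for the error message
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"collinear design: column {names[j]!r} is redundant")
        raise ValueError("collinear design matrix")


def firth_logistic(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    ci_level: float | None = 0.95,
    compute_pvalues: bool = True,
) -> FirthFit:
    """Fit logistic regression by Firth's penalized likelihood.

    ``y`` is binary with 1 = NON-REM (the modeled event).  Estimates stay
    finite under complete separation; non-convergence is flagged on the
    result rather than raised.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1 (1 = NON-REM)")
    if y.sum() == 0 or y.sum() == y.shape[0]:
        raise ValueError("both outcome classes must be present")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept", *names]
    _validate_design(X, names)

    free = np.ones(X.shape[1], dtype=bool)
    beta, ll, converged, n_iter = _firth_newton(
        X, y, free, np.zeros(X.shape[1]), max_iter, tol
    )
    fit = FirthFit(names=names, beta=beta, loglik=ll, converged=converged, n_iter=n_iter)

    if compute_pvalues:
        pvals = np.full(X.shape[1], np.nan)
        for j in range(X.shape[1]):
            if add_intercept and j == 0:
                continue
            free_j = free.copy()
            free_j[j] = False
            b0 = np.zeros(X.shape[1])
            _, ll0, _, _ = _firth_newton(X, y, free_j, b0, max_iter, tol)
            stat = max(2.0 * (ll - ll0), 0.0)
            pvals[j] = float(chi2.sf(stat, df=1))
        fit.pvalues = pvals
    if ci_level is not None:
        fit.conf_int, fit.ci_open = _profile_ci_all(
            X, y, beta, ll, ci_level, max_iter, tol, skip=0 if add_intercept else None
        )
    fit._design = (X, y)  # kept for profile CIs at other levels
    return fit


def _profile_loglik(
    X: np.ndarray, y: np.ndarray, j: int, value: float, max_iter: int, tol: float
) -> float:
    free = np.ones(X.shape[1], dtype=bool)
    free[j] = False
    b0 = np.zeros(X.shape[1])
    b0[j] = value
    _, ll, _, _ = _firth_newton(X, y, free, b0, max_iter, tol)
    return ll


def _ci_bound(
    X, y, beta_hat, ll_hat, j, target, direction, max_iter, tol, bracket_limit=20.0
) -> tuple[float, bool]:
    """One profile-CI bound by bisection on the beta scale (to 1e-6)."""

    def deficit(b: float) -> float:
        return 2.0 * (ll_hat - _profile_loglik(X, y, j, b, max_iter, tol)) - target

    lo = beta_hat[j]
    step = 0.5
    hi = lo + direction * step
    while deficit(hi) < 0:
        step *= 2.0
        hi = lo + direction * step
        if abs(hi - beta_hat[j]) > bracket_limit:
            return direction * np.inf, True
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if deficit(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(hi - lo) < 1e-6:
            break
    return 0.5 * (lo + hi), False


def _profile_ci_all(X, y, beta, ll, level, max_iter, tol, skip=None):
    target = chi2.ppf(level, df=1)
    ci = np.full((X.shape[1], 2), np.nan)
    ci_open = np.zeros((X.shape[1], 2), dtype=bool)
    for j in range(X.shape[1]):
        if skip is not None and j == skip:
            continue
        lo, open_lo = _ci_bound(X, y, beta, ll, j, target, -1.0, max_iter, tol)
        hi, open_hi = _ci_bound(X, y, beta, ll, j, target, +1.0, max_iter, tol)
        ci[j] = (np.exp(lo), np.exp(hi))
        ci_open[j] = (open_lo, open_hi)
    return ci, ci_open


def profile_ci(fit: FirthFit, level: float = 0.95) -> np.ndarray:
    """Profile penalized-likelihood CI on the odds-ratio scale.

    Bounds solve ``2[l*(b_hat) − l*_profile(b)] = chi2_1(level)`` by
    bisection to 1e-6 on the coefficient scale; a bound that cannot be
    bracketed within ±20 on that scale is reported open (±inf on the OR
    scale) and flagged.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    if not hasattr(fit, "_design"):
        raise ValueError("fit does not carry its design matrix")
    X, y = fit._design
    ci, ci_open = _profile_ci_all(X, y, fit.beta, fit.loglik, level, 100, 1e-6)
    fit.conf_int, fit.ci_open = ci, ci_open
    return ci


class FirthLogisticRegression(ClassifierMixin, BaseEstimator):
    """Binary logistic regression with Firth's Jeffreys-prior penalty.

    Drop-in classifier (fit / predict / predict_proba) whose estimates
    remain finite under separation.  Fitted attributes expose the
    association table used for reporting: ``odds_ratios_``, ``conf_int_``
    (profile-likelihood, OR scale) and ``pvalues_`` (penalized LRT).
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        max_iter: int = 100,
        tol: float = 1e-6,
        ci_level: float | None = 0.95,
        compute_pvalues: bool = True,
    ) -> None:
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.ci_level = ci_level
        self.compute_pvalues = compute_pvalues

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] != 2:
            raise ValueError("exactly two classes are required")
        y01 = (y == self.classes_[1]).astype(float)
        fit = firth_logistic(
            X,
            y01,
            add_intercept=self.fit_intercept,
            max_iter=self.max_iter,
            tol=self.tol,
            ci_level=self.ci_level,
            compute_pvalues=self.compute_pvalues,
        )
        self.fit_ = fit
        offset = 1 if self.fit_intercept else 0
        self.intercept_ = np.array([fit.beta[0] if self.fit_intercept else 0.0])
        self.coef_ = fit.beta[offset:][None, :]
        self.odds_ratios_ = fit.odds_ratios[offset:]
        self.conf_int_ = None if fit.conf_int is None else fit.conf_int[offset:]
        self.pvalues_ = None if fit.pvalues is None else fit.pvalues[offset:]
        self.converged_ = fit.converged
        self.n_iter_ = np.array([fit.n_iter])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


# ------------------------------------------------------------------- ROC


@dataclass
class RocResult:
    """ROC curve with NON-REM as the positive class."""

    auc: float
    thresholds: np.ndarray  # descending; calls are "score > threshold"
    sensitivity: np.ndarray
    specificity: np.ndarray

    def curve_points(self) -> np.ndarray:
        """(1 - specificity, sensitivity) pairs, in threshold order."""
        return np.column_stack([1.0 - self.specificity, self.sensitivity])


@dataclass
class OptimalCutoff:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    degenerate: bool = False
    orientation: float = 1.0  # threshold applies to orientation * score


def roc_curve(scores: Sequence[float], y: Sequence) -> RocResult:
    """ROC curve of a signature score against the binary outcome.

    ``y`` is 1 for NON-REM ("positive").  Thresholds sweep the unique
    score values (a sample is called positive when its score is strictly
    above the threshold); the AUC uses the Mann–Whitney rank convention,
    so tied scores contribute half a concordance.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    thresholds = np.concatenate([np.unique(scores)[::-1], [-np.inf]])
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = scores > t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    return RocResult(auc=auc, thresholds=thresholds, sensitivity=sens, specificity=spec)


def optimal_threshold(roc: RocResult, scores: Sequence[float], y: Sequence) -> OptimalCutoff:
    """Operating point maximizing Youden's J, ties broken toward higher
    specificity.  Returns sensitivity/specificity/PPV/NPV at the cutoff
    (PPV = TP/(TP+FP) with NON-REM positive)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    j_stat = roc.sensitivity + roc.specificity - 1.0
    best = max(
        range(len(roc.thresholds)),
        key=lambda i: (j_stat[i], roc.specificity[i]),
    )
    t = float(roc.thresholds[best])
    pred = scores > t
    tp = float((pred & (y == 1)).sum())
    fp = float((pred & (y == 0)).sum())
    tn = float((~pred & (y == 0)).sum())
    fn = float((~pred & (y == 1)).sum())
    ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    npv = tn / (tn + fn) if (tn + fn) > 0 else np.nan
    return OptimalCutoff(
        threshold=t,
        youden_j=float(j_stat[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        ppv=ppv,
        npv=npv,
        degenerate=bool(np.isclose(j_stat[best], 0.0)),
    )


def auc_bootstrap_ci(
    scores: Sequence[float],
    y: Sequence,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (extension beyond the core
    reporting; resamples patients with replacement, stratified by class)."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    stats = []
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        stats.append(roc_curve(scores[idx], y[idx]).auc)
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
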