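"""L2-penalized logistic classification with leave-one-out evaluation.

The classifier discriminates cancer (SEC or AEC) from healthy samples using
the selected miRNA expression profiles.  ``RidgeLogit`` is a small
statsmodels-style model object: it minimizes

    sum_i log(1 + exp(-s_i * eta_i)) + (penalty / 2) * ||w||^2

(s_i = +/-1, intercept unpenalized) by damped Newton iterations to a
gradient norm below 1e-8, so fits are exactly reproducible.  Model
performance is scored by leave-one-out cross-validation with feature
standardization recomputed inside every training fold (no information from
the held-out sample leaks into the fit), and summarized by the ROC curve,
the tie-aware pairwise AUC and a DeLong 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve

from .preprocess import ConvergenceError

logger = logging.getLogger(__name__)

CANCER_COHORTS = ("SEC", "AEC")


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        y = y.astype(int)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    return y.astype(float)


class RidgeLogit:
    """Logistic regression with an L2 penalty on the weights.

    Parameters
    ----------
    exog : (n, p) feature matrix; callers standardize with training-fold
        statistics before fitting.
    endog : binary labels (1 = cancer).
    penalty : ridge weight lambda (> 0 guarantees a finite optimum even
        under perfect separation).
    """

    def __init__(self, exog, endog, penalty: float = 1.0) -> None:
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("exog must be a 2-D matrix with >= 1 feature")
        y = _as_binary(endog)
        if y.size != X.shape[0]:
            raise ValueError(f"{y.size} labels for {X.shape[0]} rows")
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present to fit a classifier")
        if penalty < 0:
            raise ValueError(f"penalty must be >= 0, got {penalty}")
        self.exog = X
        self.endog = y
        self.penalty = float(penalty)

    def _objective(self, beta, Xd):
        eta = Xd @ beta
        s = 2.0 * self.endog - 1.0
        nll = np.logaddexp(0.0, -s * eta).sum()
        return nll + 0.5 * self.penalty * np.dot(beta[1:], beta[1:])

    def _grad(self, beta, Xd):
        eta = Xd @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g = Xd.T @ (p - self.endog)
        g[1:] += self.penalty * beta[1:]
        return g, p

    def fit(self, gtol: float = 1e-8, maxiter: int = 100) -> "RidgeLogitResults":
        """Damped Newton (IRLS) iterations until the penalized-objective
        gradient norm drops below ``gtol``; deterministic start at zero."""
        n, p = self.exog.shape
        Xd = np.column_stack([np.ones(n), self.exog])
        pen = np.full(p + 1, self.penalty)
        pen[0] = 0.0
        beta = np.zeros(p + 1)
        obj = self._objective(beta, Xd)
        for it in range(1, maxiter + 1):
            g, prob = self._grad(beta, Xd)
            gnorm = float(np.linalg.norm(g))
            if gnorm <= gtol:
                return RidgeLogitResults(self, beta, gnorm, it - 1, converged=True)
            w = np.maximum(prob * (1.0 - prob), 1e-12)
            H = (Xd * w[:, None]).T @ Xd + np.diag(pen)
            step = np.linalg.solve(H, g)
            # backtracking keeps the iteration globally convergent
            t = 1.0
            for _ in range(60):
                cand = beta - t * step
                cand_obj = self._objective(cand, Xd)
                if cand_obj <= obj:
                    break
                t *= 0.5
            beta, obj = cand, cand_obj
        g, _ = self._grad(beta, Xd)
        raise ConvergenceError(
            f"ridge logistic fit did not converge in {maxiter} Newton iterations "
            f"(gradient norm {np.linalg.norm(g):.3e}, tolerance {gtol:.1e})"
        )


@dataclass(frozen=True)
class RidgeLogitResults:
    model: RidgeLogit
    _beta: np.ndarray
    grad_norm: float
    n_iter: int
    converged: bool

    @property
    def intercept(self) -> float:
        return float(self._beta[0])

    @property
    def weights(self) -> np.ndarray:
        return self._beta[1:].copy()

    def predict_proba(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.intercept + X @ self._beta[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "Ridge logistic regression",
            f"  n obs      : {self.model.exog.shape[0]}",
            f"  n features : {self.model.exog.shape[1]}",
            f"  penalty    : {self.model.penalty}",
            f"  iterations : {self.n_iter} (|grad| = {self.grad_norm:.2e})",
            f"  intercept  : {self.intercept:+.4f}",
        ]
        lines += [f"  w[{i}]       : {w:+.4f}" for i, w in enumerate(self.weights)]
        return "\n".join(lines)


def fit_l2_logistic(features, labels, penalty: float = 1.0):
    """Fit and return (weights, intercept); thin functional wrapper."""
    res = RidgeLogit(features, labels, penalty).fit()
    return res.weights, res.intercept


def _standardize(train: np.ndarray, other: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: centred to zero
    return (train - mean) / sd, (other - mean) / sd


def loocv_scores(features, labels, penalty: float = 1.0) -> np.ndarray:
    """Held-out predicted cancer probability for every sample.

    Each sample is scored by a model trained on the other n-1 samples;
    standardization statistics are recomputed on each training fold.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    y = _as_binary(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 samples, got {n}")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("both classes need >= 2 members for LOOCV")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"fold {i} (holding out sample index {i}) has a single class")
        X_tr, X_te = _standardize(X[mask], X[[i]])
        res = RidgeLogit(X_tr, y_tr, penalty).fit()
        scores[i] = res.predict_proba(X_te)[0]
    return scores


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray


def roc_auc(scores, labels) -> tuple[ROCCurve, float]:
    """ROC curve and pairwise AUC (ties between a cancer and a healthy score
    credited 0.5, the Mann-Whitney convention)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr), float(auc)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong placement-value AUC and variance."""
    m, n = pos.size, neg.size
    # structural components: P(pos_i beats a random neg), and vice versa
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n
    v01 = np.empty(n)
    for j, x in enumerate(neg):
        v01[j] = (np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, truncated to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("confidence interval requires >= 2 samples per class")
    auc, var = _delong_variance(pos, neg)
    if var <= 0:
        logger.warning(
            "degenerate DeLong variance (AUC = %.3f); interval collapses to the point estimate",
            auc,
        )
        return float(auc), float(auc)
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def per_feature_auc(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    directions: dict[str, str],
    level: float = 0.95,
) -> pd.DataFrame:
    """Single-miRNA AUC table in the style of a marker report.

    Each feature's expression value is used directly as the classifier
    score; features labelled ``down`` are scored by their negated expression
    so that the reported AUC measures discrimination with cancer high for
    both marker directions (the direction column preserves the original
    orientation).
    """
    unknown = [f for f in directions if f not in expr.index]
    if unknown:
        raise KeyError(f"features not in the expression matrix: {unknown}")
    meta_idx = meta.set_index("sample_id")
    cols = [c for c in expr.columns if c in meta_idx.index]
    y = meta_idx.loc[cols, "cohort"].isin(CANCER_COHORTS).astype(int).to_numpy()
    rows = []
    for fid, direction in directions.items():
        vals = expr.loc[fid, cols].to_numpy(dtype=float)
        score = -vals if direction == "down" else vals
        _, auc = roc_auc(score, y)
        lo, hi = auc_ci(score, y, level=level)
        rows.append((fid, direction, auc, lo, hi))
    return pd.DataFrame(rows, columns=["feature_id", "direction", "auc", "ci_low", "ci_high"])


@dataclass
class ClassifierEval:
    """LOOCV evaluation of the joint marker panel."""

    sample_ids: list[str]
    labels: np.ndarray
    loocv: np.ndarray
    roc: ROCCurve
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    penalty: float

    def summary(self) -> str:
        return (
            "Leave-one-out classifier evaluation\n"
            f"  samples : {len(self.sample_ids)} "
            f"({int(self.labels.sum())} cancer / {int((1 - self.labels).sum())} healthy)\n"
            f"  penalty : {self.penalty}\n"
            f"  AUC     : {self.auc:.3f} "
            f"(95% CI {self.auc_ci_low:.3f}-{self.auc_ci_high:.3f})"
        )


def evaluate_classifier(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    features: list[str],
    penalty: float = 1.0,
) -> ClassifierEval:
    """LOOCV the joint panel: cancer (SEC+AEC) vs healthy on ``features``."""
    missing = [f for f in features if f not in expr.index]
    if missing:
        raise KeyError(f"panel features not in the expression matrix: {missing}")
    meta_idx = meta.set_index("sample_id")
    cols = [c for c in expr.columns if c in meta_idx.index]
    y = meta_idx.loc[cols, "cohort"].isin(CANCER_COHORTS).astype(int).to_numpy()
    X = expr.loc[features, cols].to_numpy(dtype=float).T
    scores = loocv_scores(X, y, penalty=penalty)
    curve, auc = roc_auc(scores, y)
    lo, hi = auc_ci(scores, y)
    return ClassifierEval(
        sample_ids=cols, labels=y.astype(float), loocv=scores, roc=curve,
        auc=auc, auc_ci_low=lo, auc_ci_high=hi, penalty=penalty,
    )


def plot_roc(curve: ROCCurve, auc: float, path) -> None:
    """Write a basic ROC figure (PNG) for the run report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, lw=1.5, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
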