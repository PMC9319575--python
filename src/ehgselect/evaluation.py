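"""Classification and imbalance-aware evaluation.

The classifier throughout is linear discriminant analysis: a shared-
covariance Gaussian discriminant whose posterior for the preterm class is
a logistic function of a linear score. Performance is reported with
threshold-independent metrics — area under the ROC curve (AUC) and
average precision (AP, step-summed area under the precision-recall
curve) — which are not biased by the 16 % prevalence, plus threshold-
dependent metrics (recall, specificity, precision, F1, G-mean) at
operative points chosen to maximise F1 or G-mean. The positive class is
always preterm.

Paired strategy comparisons over repeated holdout partitions use
D'Agostino's K^2 normality test, one-way repeated-measures ANOVA with
partitions as subjects, and Tukey's test on the RANOVA error term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger("ehgselect")


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Pooled-covariance linear discriminant in score form w.x + b."""

    coef: np.ndarray
    intercept: float
    means: np.ndarray  # (2, p): row 0 = class 0, row 1 = class 1
    priors: np.ndarray
    kept: np.ndarray  # boolean mask of retained (non-constant) features
    feature_names: list[str] | None = None


def lda_fit(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-9,
    feature_names: list[str] | None = None,
) -> LDAModel:
    """Fit the shared-covariance Gaussian discriminant.

    Features with zero pooled within-class variance are dropped with a
    warning; a ridge term ridge * trace(S)/p * I keeps the pooled
    covariance invertible when rank-deficient (duplicated or collinear
    columns), which in the small-ridge limit reproduces the minimum-norm
    discriminant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("both classes (0 and 1) must be present")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 rows per class")

    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    d0, d1 = X0 - mu0, X1 - mu1
    pooled = (d0.T @ d0 + d1.T @ d1) / (n0 + n1 - 2)

    var = np.diag(pooled).copy()
    kept = var > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature(s) before LDA",
            RuntimeWarning, stacklevel=2)
        pooled = pooled[np.ix_(kept, kept)]
        mu0, mu1 = mu0[kept], mu1[kept]
    p = pooled.shape[0]
    if p == 0:
        raise ValueError("no non-constant features left")
    lam = ridge * np.trace(pooled) / p
    sigma = pooled + lam * np.eye(p)
    try:
        w = np.linalg.solve(sigma, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(sigma, mu1 - mu0, rcond=None)[0]
    priors = np.array([n0, n1]) / (n0 + n1)
    b = float(-w @ (mu0 + mu1) / 2.0 + np.log(priors[1] / priors[0]))
    return LDAModel(coef=w, intercept=b, means=np.stack([mu0, mu1]),
                    priors=priors, kept=kept, feature_names=feature_names)


def lda_posterior(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive (preterm) class per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = X[:, model.kept] @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# threshold-independent metrics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the empirical ROC (trapezoid; ties by the rank /
    Mann-Whitney equivalence)."""
    return float(roc_auc_score(np.asarray(labels, int), np.asarray(scores, float)))


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over descending score thresholds."""
    return float(average_precision_score(np.asarray(labels, int),
                                         np.asarray(scores, float)))


def combined_score(auc_value: float, ap_value: float) -> float:
    return (auc_value + ap_value) / 2.0


# ---------------------------------------------------------------------------
# threshold-dependent metrics and operative points
# ---------------------------------------------------------------------------

def confusion_counts(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, fn, tn


def threshold_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Recall, specificity, precision, F1 and G-mean at one threshold.

    A row is predicted preterm when its score >= threshold. Precision is
    NaN when nothing is predicted positive (F1 is then 0).
    """
    tp, fp, fn, tn = confusion_counts(scores, labels, threshold)
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (fp + tn) if fp + tn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    if tp + fp == 0 or np.isnan(precision) or recall + precision == 0:
        f1 = 0.0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    gmean = float(np.sqrt(recall * specificity)) if not (
        np.isnan(recall) or np.isnan(specificity)) else float("nan")
    return {"recall": recall, "specificity": specificity,
            "precision": precision, "F1": f1, "G-mean": gmean}


def f1_score_binary(pred: np.ndarray, labels: np.ndarray) -> float:
    """F1 of the positive class from hard predictions (fast path for the
    GA fitness loop)."""
    pred = np.asarray(pred, bool)
    labels = np.asarray(labels, int)
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def operative_point(scores, labels, criterion: str = "F1") -> float:
    """Score threshold maximising F1 or G-mean.

    Candidates are the unique observed scores; ties resolve to the lowest
    threshold (favouring recall).
    """
    if criterion not in ("F1", "G-mean"):
        raise ValueError("criterion must be 'F1' or 'G-mean'")
    scores = np.asarray(scores, float)
    candidates = np.unique(scores)
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        v = threshold_metrics(scores, labels, t)[criterion]
        if np.isnan(v):
            continue
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return float(best_t)


# ---------------------------------------------------------------------------
# per-strategy result container
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-partition AUC and AP for one (feature subset, resampling) cell."""

    auc: np.ndarray
    ap: np.ndarray
    operative: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.auc = np.asarray(self.auc, float)
        self.ap = np.asarray(self.ap, float)
        if self.auc.shape != self.ap.shape:
            raise ValueError("per-partition AUC and AP lengths differ")

    @property
    def combined(self) -> np.ndarray:
        return (self.auc + self.ap) / 2.0

    def summary(self) -> dict[str, float]:
        return {
            "auc_mean": float(self.auc.mean()), "auc_sd": float(self.auc.std(ddof=1)),
            "ap_mean": float(self.ap.mean()), "ap_sd": float(self.ap.std(ddof=1)),
            "combined_mean": float(self.combined.mean()),
            "combined_sd": float(self.combined.std(ddof=1)),
        }


# ---------------------------------------------------------------------------
# statistical comparison across strategies
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    method_names: list[str]
    normality_p: np.ndarray
    anova_f: float
    anova_p: float
    tukey_p: np.ndarray  # (k, k) pairwise
    groups: list[set[str]]
    mse: float
    df_error: int


def rm_anova(matrix: np.ndarray) -> tuple[float, float, float, int]:
    """One-way repeated-measures ANOVA (subjects = partitions).

    Returns (F, p, MS_error, df_error). No sphericity correction.
    """
    matrix = np.asarray(matrix, float)
    n, k = matrix.shape
    grand = matrix.mean()
    col_means = matrix.mean(axis=0)
    row_means = matrix.mean(axis=1)
    ss_method = n * ((col_means - grand) ** 2).sum()
    ss_subject = k * ((row_means - grand) ** 2).sum()
    ss_total = ((matrix - grand) ** 2).sum()
    ss_error = ss_total - ss_method - ss_subject
    df_method = k - 1
    df_error = (n - 1) * (k - 1)
    ms_method = ss_method / df_method
    ms_error = ss_error / df_error
    if ms_error <= 0:
        # degenerate (e.g. identical columns): no within-subject variation
        f = 0.0 if ms_method <= 0 else float("inf")
        p = 1.0 if ms_method <= 0 else 0.0
        return f, p, 0.0, df_error
    f = ms_method / ms_error
    return float(f), float(stats.f.sf(f, df_method, df_error)), float(ms_error), df_error


def compare_strategies(
    score_matrix: np.ndarray, method_names: list[str], alpha: float = 0.05
) -> ComparisonResult:
    """Paired comparison of strategies over repeated partitions.

    Per-method D'Agostino K^2 normality p-values, RANOVA F/p, Tukey
    pairwise p-values on the RANOVA error term, and the partition of
    methods into homogeneous groups (connected components of the
    'not significantly different' graph at ``alpha``).
    """
    matrix = np.asarray(score_matrix, float)
    if matrix.ndim != 2:
        raise ValueError("score_matrix must be partitions x methods")
    n, k = matrix.shape
    if k != len(method_names):
        raise ValueError("method_names length does not match matrix columns")
    if np.isnan(matrix).any():
        raise ValueError("incomplete pairing: score matrix contains NaN")

    normality_p = np.full(k, np.nan)
    for j in range(k):
        col = matrix[:, j]
        if np.ptp(col) > 0 and n >= 20:
            normality_p[j] = stats.normaltest(col).pvalue

    f, p, mse, df_error = rm_anova(matrix)

    col_means = matrix.mean(axis=0)
    tukey_p = np.ones((k, k))
    if mse > 0:
        se = np.sqrt(mse / n)
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(col_means[i] - col_means[j]) / se
                pv = float(stats.studentized_range.sf(q, k, df_error))
                tukey_p[i, j] = tukey_p[j, i] = pv
    elif np.ptp(col_means) > 0:
        tukey_p[:] = 0.0
        np.fill_diagonal(tukey_p, 1.0)

    # homogeneous groups: connected components of non-significant pairs
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if tukey_p[i, j] > alpha:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i in range(k):
        comps.setdefault(find(i), set()).add(method_names[i])
    groups = sorted(comps.values(), key=lambda g: sorted(g))

    return ComparisonResult(
        method_names=list(method_names), normality_p=normality_p,
        anova_f=f, anova_p=p, tukey_p=tukey_p, groups=groups,
        mse=mse, df_error=df_error)
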