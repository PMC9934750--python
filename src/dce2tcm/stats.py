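"""Biomarker statistics for model comparison and tissue discrimination.

The battery mirrors standard practice for evaluating competing kinetic
models and their parameters as cancer biomarkers: a paired t-test on
voxelwise fit RMSE (does the richer model fit better?), Pearson correlation
between corresponding parameters of the two models, one-way ANOVA with
Tukey HSD across tissue classes, ROC/AUC with a Hanley-McNeil 95% CI for
single-parameter discrimination, and binary logistic regression (in-sample)
to score parameter combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RocResult",
    "GroupComparison",
    "LogisticCombination",
    "paired_ttest",
    "pearson_r",
    "anova_tukey",
    "roc_auc",
    "logistic_combine",
]


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95_low: float
    ci95_high: float
    n_pos: int
    n_neg: int


@dataclass
class GroupComparison:
    groups: dict  # name -> values
    anova_f: float
    anova_p: float
    tukey_pairwise: dict  # frozenset({a, b}) -> adjusted p


@dataclass
class LogisticCombination:
    intercept: float
    coef: np.ndarray
    scores: np.ndarray  # in-sample linear predictor
    roc: RocResult
    converged: bool


def paired_ttest(a, b):
    """Two-sided paired t-test; returns (t, df, p) with df = n - 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("a and b must be equal-length 1-D vectors with n >= 2")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, a.size - 1, 1.0  # identical pairs: no difference
        raise ValueError("zero-variance nonzero differences: t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def pearson_r(x, y):
    """Pearson product-moment correlation with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-constant inputs resolve to nan below
        r, p = sps.pearsonr(x, y)
    if not np.isfinite(r):
        raise ValueError("correlation undefined for (near-)constant input")
    return float(r), float(p)


def anova_tukey(groups: dict) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD adjusted pairwise comparisons.

    ``groups`` maps group name -> 1-D value vector (each n >= 2); unequal
    group sizes use the Tukey-Kramer form of the studentized-range test.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 members")
    names = list(arrays)
    f, p = sps.f_oneway(*arrays.values())
    if not np.isfinite(f):  # all groups identical constant
        f, p = 0.0, 1.0
    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([[k] * arrays[k].size for k in names])
    tk = pairwise_tukeyhsd(values, labels)
    pairwise = {}
    for (g1, g2), padj in zip(
        [(str(r[0]), str(r[1])) for r in tk.summary().data[1:]], np.atleast_1d(tk.pvalues)
    ):
        pairwise[frozenset((g1, g2))] = float(padj)
    return GroupComparison(groups=arrays, anova_f=float(f), anova_p=float(p), tukey_pairwise=pairwise)


def roc_auc(pos, neg) -> RocResult:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2),
    with the Hanley-McNeil 95% confidence interval."""
    pos = np.asarray(pos, dtype=float).ravel()
    neg = np.asarray(neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    n_pos, n_neg = pos.size, neg.size
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    a = float(u / (n_pos * n_neg))
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return RocResult(
        auc=a,
        ci95_low=max(0.0, a - 1.959963984540054 * se),
        ci95_high=min(1.0, a + 1.959963984540054 * se),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def logistic_combine(features, labels) -> LogisticCombination:
    """Combine parameters by maximum-likelihood binary logistic regression.

    Unregularized fit with intercept (Newton/IRLS); the combined score is
    the in-sample linear predictor, scored by :func:`roc_auc`.  Perfect
    separation is flagged as non-converged but an AUC is still reported
    from the final linear predictor.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("features and labels must have matching sample counts")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 samples per class")

    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(method="newton", tol=1e-10, maxiter=200, disp=0)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:  # perfect separation or singular Hessian
            res = sm.Logit(y, Xc).fit(method="bfgs", maxiter=200, disp=0, skip_hessian=True)
            params = np.asarray(res.params, dtype=float)
            converged = False
    scores = Xc @ params
    roc = roc_auc(scores[y == 1], scores[y == 0])
    return LogisticCombination(
        intercept=float(params[0]), coef=params[1:], scores=scores, roc=roc, converged=converged
    )
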