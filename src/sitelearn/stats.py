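"""Rank-based AUC, Mann-Whitney inference and report-level statistics.

The AUC here is the rank (Mann-Whitney) formulation: the fraction of
case-control pairs where the case scores higher, ties counted half.  The
associated U statistic is U = AUC * n_case * n_control; its two-sided
p-value comes from exact enumeration of all label assignments when
n_case + n_control <= 12 and otherwise from the normal approximation with
tie-corrected null variance and continuity correction.  The 95% confidence
interval uses the Hanley-McNeil variance estimate, truncated to [0, 1].
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "auc_rank",
    "mwu_auc_inference",
    "bonferroni",
    "secondary_metrics",
    "site_size_performance_correlation",
    "EXACT_ENUMERATION_MAX_N",
]

#: exact p-value enumeration is used when n_case + n_control is at most this
EXACT_ENUMERATION_MAX_N = 12


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("AUC undefined: a class is absent")
    return scores, labels, cases, controls


def auc_rank(scores, labels) -> float:
    """AUC = (#pairs case>control + 0.5 * ties) / (n_case * n_control).

    Computed from the rank-sum identity (midranks), which equals the
    pairwise definition exactly.
    """
    scores, labels, cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    ranks = sps.rankdata(scores)  # average-rank ties
    r1 = ranks[labels == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _u_of_subset(ranks_all: np.ndarray, subset: tuple[int, ...], n1: int) -> float:
    return ranks_all[list(subset)].sum() - n1 * (n1 + 1) / 2.0


def _exact_two_sided_p(scores: np.ndarray, labels: np.ndarray) -> float:
    """Permutation-exact two-sided p: 2 * min(tail probabilities), capped at 1.

    Enumerates every assignment of which observations are cases (ties kept
    in place via midranks), so the null distribution of U is exact.
    """
    n = len(scores)
    n1 = int((labels == 1).sum())
    ranks_all = sps.rankdata(scores)
    u_obs = _u_of_subset(ranks_all, tuple(np.flatnonzero(labels == 1)), n1)
    us = np.array([
        _u_of_subset(ranks_all, c, n1) for c in combinations(range(n), n1)
    ])
    eps = 1e-9
    p_hi = np.mean(us >= u_obs - eps)
    p_lo = np.mean(us <= u_obs + eps)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def _normal_two_sided_p(scores: np.ndarray, labels: np.ndarray) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    n = len(scores)
    n1 = int((labels == 1).sum())
    n0 = n - n1
    u = auc_rank(scores, labels) * n1 * n0
    mu = n1 * n0 / 2.0
    _, counts = np.unique(scores, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all scores identical
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def hanley_mcneil_ci(auc: float, n1: int, n0: int, alpha: float = 0.05
                     ) -> tuple[float, float]:
    """Hanley-McNeil AUC variance with normal quantiles, truncated to [0, 1]."""
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    var = max(var, 0.0)
    half = sps.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def mwu_auc_inference(scores, labels, alpha: float = 0.05
                      ) -> tuple[float, float, tuple[float, float]]:
    """(U, two-sided p, (1-alpha) CI) for the rank AUC of scores vs labels."""
    scores, labels, cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    auc = auc_rank(scores, labels)
    u = auc * n1 * n0
    if n1 + n0 <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(scores, labels)
    else:
        p = _normal_two_sided_p(scores, labels)
    ci = hanley_mcneil_ci(auc, n1, n0, alpha)
    return float(u), float(p), ci


def bonferroni(p_values, alpha: float = 0.05, m: int = 1) -> np.ndarray:
    """Family-wise significance flags: p <= alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    return p <= alpha / m


def secondary_metrics(scores, labels, threshold: float = 0.5
                      ) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity) at a hard threshold."""
    scores, labels, cases, controls = _split(scores, labels)
    pred = scores > threshold
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return ((sens + spec) / 2.0, sens, spec)


def site_size_performance_correlation(per_site_auc, per_site_n
                                      ) -> tuple[float, float]:
    """Spearman rank correlation of site size vs mean site AUC (two-sided p)."""
    auc = np.asarray(per_site_auc, dtype=float)
    n = np.asarray(per_site_n, dtype=float)
    if len(auc) < 3:
        raise ValidationError("need at least 3 sites")
    if np.allclose(auc, auc[0]) or np.allclose(n, n[0]):
        raise ValidationError("correlation undefined for constant inputs")
    rho, p = sps.spearmanr(n, auc)
    return float(rho), float(p)
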