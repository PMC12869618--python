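"""Test-retest reliability for two-session pair-metric matrices.

The intraclass correlation assumes an additive, separable ANOVA model that
warping-based distances violate, so reliability is summarized instead by
two |t|-style statistics and their ratio:

* within-subject: paired-t magnitude of the session difference per pair,
  |t|_within = |mean(d)| / (sd(d)/sqrt(n)) — small means sessions agree;
* between-subject: a non-parametric analogue on session 1 only,
  |t|_between = median(|s1_i - mean(s1)|) / (IQR/sqrt(n)) — large means
  subjects are distinguishable;
* composite trt = 1 - |t|_within / |t|_between, approaching 1 for highly
  reliable metrics.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class ReliabilityResult:
    t_within: np.ndarray
    t_between: np.ndarray
    trt: np.ndarray


def within_subject_stat(
    session1: np.ndarray, session2: np.ndarray, use_sqrt_n: bool = True
) -> np.ndarray:
    """Per-pair paired-t magnitude between sessions.

    All-zero differences (sessions identical for a pair) give 0 — perfect
    within-subject consistency; zero-sd differences with a nonzero mean
    give +inf with a warning. ``use_sqrt_n=False`` switches the denominator
    from sd/sqrt(n) to sd/n (the literal typographic reading).
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"session shapes differ: {s1.shape} vs {s2.shape}")
    s1, s2 = np.atleast_2d(s1), np.atleast_2d(s2)
    n = s1.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    d = s1 - s2
    mean_d = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    scale = np.sqrt(n) if use_sqrt_n else float(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_d) / (sd / scale)
    # treat sd at floating-point round-off scale as exactly zero
    degenerate = sd <= 1e-12 * np.maximum(np.abs(d).max(axis=0), 1.0)
    if np.any(degenerate):
        t = np.where(degenerate & (mean_d == 0), 0.0, t)  # 0/0 -> perfect consistency
        t = np.where(degenerate & (mean_d != 0), np.inf, t)
        if np.any(degenerate & (mean_d != 0)):
            warnings.warn(
                "zero-sd session differences with nonzero mean; |t|_within set to +inf",
                stacklevel=2,
            )
    return t


def between_subject_stat(session1: np.ndarray, use_sqrt_n: bool = True) -> np.ndarray:
    """Per-pair non-parametric between-subject spread statistic (session 1 only).

    d_i = |s1_i - mean(s1)|; statistic = median(d) / (IQR(d)/sqrt(n)).
    IQR = 0 gives a +inf sentinel with a warning.
    """
    s1 = np.atleast_2d(np.asarray(session1, dtype=float))
    n = s1.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects for a defined IQR, got {n}")
    d = np.abs(s1 - s1.mean(axis=0, keepdims=True))
    med = np.median(d, axis=0)
    q75, q25 = np.percentile(d, [75, 25], axis=0)
    iqr = q75 - q25
    scale = np.sqrt(n) if use_sqrt_n else float(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = med / (iqr / scale)
    if np.any(iqr == 0):
        warnings.warn("zero IQR of between-subject differences; |t|_between set to +inf", stacklevel=2)
        t = np.where(iqr == 0, np.inf, t)
    return t


def trt_score(
    session1: np.ndarray, session2: np.ndarray, use_sqrt_n: bool = True
) -> ReliabilityResult:
    """Composite test-retest reliability trt = 1 - |t|_within / |t|_between per pair."""
    tw = within_subject_stat(session1, session2, use_sqrt_n=use_sqrt_n)
    tb = between_subject_stat(session1, use_sqrt_n=use_sqrt_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        trt = 1.0 - tw / tb
    trt = np.where(np.isinf(tb) & np.isfinite(tw), 1.0, trt)  # infinite spread dominates
    trt = np.where(np.isinf(tw) & np.isfinite(tb), -np.inf, trt)
    trt = np.where(np.isinf(tw) & np.isinf(tb), np.nan, trt)
    return ReliabilityResult(t_within=tw, t_between=tb, trt=np.asarray(trt))


def trt_compare(trt_a: np.ndarray, trt_b: np.ndarray):
    """Rank two methods' trt scores across pairs and test their paired difference.

    Per pair the two methods are ranked (rank 1 = higher trt = more
    reliable, average ranks on ties); returns (mean_rank_a, mean_rank_b,
    signed-rank p). Identical inputs give p = 1 by convention.
    """
    a = np.asarray(trt_a, dtype=float)
    b = np.asarray(trt_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("trt vectors must be 1-D and the same length")
    ranks = rankdata(-np.vstack([a, b]), axis=0, method="average")
    mean_rank_a, mean_rank_b = float(ranks[0].mean()), float(ranks[1].mean())
    if np.allclose(a, b):
        p = 1.0
    else:
        p = float(wilcoxon(a, b).pvalue)
    return mean_rank_a, mean_rank_b, p


def trt_rank_table(trt_by_method: dict[str, np.ndarray], alpha: float = 0.05):
    """Mean rank per method plus BH-adjusted pairwise signed-rank p-values.

    The workflow behind critical-difference-style comparisons of metric
    variants (e.g. nDTW at several gammas against a correlation benchmark).
    Returns (mean_ranks: dict, comparisons: list of (name_a, name_b, p_raw,
    p_adj, reject)).
    """
    names = list(trt_by_method)
    mat = np.vstack([np.asarray(trt_by_method[n], dtype=float) for n in names])
    ranks = rankdata(-mat, axis=0, method="average")
    mean_ranks = {n: float(ranks[i].mean()) for i, n in enumerate(names)}
    pairs, p_raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = mat[i], mat[j]
            p = 1.0 if np.allclose(a, b) else float(wilcoxon(a, b).pvalue)
            pairs.append((names[i], names[j]))
            p_raw.append(p)
    if not pairs:
        return mean_ranks, []
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    comparisons = [
        (na, nb, pr, pa, bool(rj))
        for (na, nb), pr, pa, rj in zip(pairs, p_raw, p_adj, reject)
    ]
    return mean_ranks, comparisons
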