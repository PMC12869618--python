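"""Window-constrained, gamma-parameterized dynamic time warping.

The pointwise cost is lambda_gamma(a, b) = |a - b|**gamma: gamma > 1
emphasizes large amplitude disparities, gamma < 1 small ones, gamma = 1 is
the balance point; gamma = 2 makes the total distance D the energy of the
aligned difference signal and the normalized distance Dn = D/L its power.
Alignment is restricted to a Sakoe-Chiba band |i - j| <= w, which both
bounds compute and prevents pathological singularities; endpoints are
anchored, and the warping path is monotone with unit steps.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit


@dataclasses.dataclass(frozen=True)
class DtwParams:
    """DTW hyperparameters: cost exponent gamma and window half-width (samples)."""

    gamma: float = 1.5
    window: int = 45

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if int(self.window) < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        object.__setattr__(self, "window", int(self.window))


@dataclasses.dataclass
class WarpAlignment:
    """An optimal warping path with per-step aligned costs.

    ``path`` is an (L, 2) integer array of 0-based index pairs
    (phi_x(tau), phi_y(tau)); ``per_step_cost[tau]`` is
    |x[phi_x(tau)] - y[phi_y(tau)]|**gamma, so D = per_step_cost.sum()
    and Dn = D / L.
    """

    path: np.ndarray
    per_step_cost: np.ndarray
    D: float
    Dn: float
    gamma: float
    window: int

    @property
    def L(self) -> int:
        return self.path.shape[0]


def gamma_cost(a, b, gamma: float):
    """Pointwise amplitude-disparity cost |a - b|**gamma (elementwise on arrays)."""
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) ** gamma


@njit(cache=True)
def _dtw_fill(x, y, gamma, w):
    """DP fill of the cumulative cost matrix within the band.

    cm[i, j] holds the minimal cumulative cost of aligning x[:i] with
    y[:j]; cm[0, 0] = 0 and everything else starts at +inf, so paths are
    anchored at both ends.
    """
    n = x.shape[0]
    m = y.shape[0]
    cm = np.full((n + 1, m + 1), np.inf)
    cm[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = max(1, i - w)
        j_hi = min(m, i + w)
        for j in range(j_lo, j_hi + 1):
            c = abs(x[i - 1] - y[j - 1]) ** gamma
            best = cm[i - 1, j - 1]
            if cm[i - 1, j] < best:
                best = cm[i - 1, j]
            if cm[i, j - 1] < best:
                best = cm[i, j - 1]
            cm[i, j] = c + best
    return cm


@njit(cache=True)
def _dtw_backtrack(cm, n, m):
    """Recover a minimizing path, ties broken diagonal, then (i-1, j), then (i, j-1)."""
    max_len = n + m - 1
    path = np.empty((max_len, 2), dtype=np.int64)
    i, j = n, m
    pos = max_len
    while i > 0 or j > 0:
        pos -= 1
        path[pos, 0] = i - 1
        path[pos, 1] = j - 1
        if i == 1 and j == 1:
            break
        diag = cm[i - 1, j - 1] if i > 0 and j > 0 else np.inf
        up = cm[i - 1, j] if i > 0 else np.inf
        left = cm[i, j - 1] if j > 0 else np.inf
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    return path[pos:]


def dtw_align(x, y, params: DtwParams) -> WarpAlignment:
    """Optimal windowed alignment of two series.

    Returns the minimizing warping path (ties resolved deterministically:
    diagonal predecessor preferred), the per-step costs along it, the total
    distance D (= DP terminal cell) and Dn = D / L.

    Raises
    ------
    ValueError
        If inputs are non-finite, too short, or the length difference
        exceeds the window (no monotone anchored path can exist in the band).
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("dtw_align expects 1-D series")
    n, m = x.shape[0], y.shape[0]
    if n < 2 or m < 2:
        raise ValueError(f"series too short for alignment (N={n}, M={m}; need >= 2)")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input series")
    w = int(params.window)
    if abs(n - m) > w:
        raise ValueError(
            f"window w={w} infeasible: |N - M| = {abs(n - m)} exceeds it; "
            "no anchored path fits in the band"
        )
    cm = _dtw_fill(x, y, float(params.gamma), w)
    D = float(cm[n, m])
    path = np.asarray(_dtw_backtrack(cm, n, m))
    per_step = np.abs(x[path[:, 0]] - y[path[:, 1]]) ** params.gamma
    # D must equal the path cost; guards against backtracking defects
    assert abs(per_step.sum() - D) <= 1e-9 * max(1.0, D)
    return WarpAlignment(
        path=path,
        per_step_cost=per_step,
        D=D,
        Dn=D / path.shape[0],
        gamma=float(params.gamma),
        window=w,
    )


def ndtw(x, y, params: DtwParams) -> float:
    """Normalized DTW distance Dn = D / L: the mean aligned cost.

    Dn is the timing-invariant amplitude disparity between x and y —
    low Dn is "convergence" (proportionate amplitudes after alignment),
    high Dn "divergence".
    """
    return dtw_align(x, y, params).Dn


def pairwise_ndtw(panel, params: DtwParams) -> np.ndarray:
    """Dn for every unordered channel pair of every subject.

    Returns an (n_subjects, n_pairs) array; the pair axis follows
    :func:`ndtwkit.panel.channel_pairs` (row-major i < j).
    """
    from .panel import channel_pairs

    panel.require_finite()
    if panel.n_channels < 2:
        raise ValueError("pairwise_ndtw needs at least 2 channels")
    pairs = channel_pairs(panel.n_channels)
    out = np.empty((panel.n_subjects, len(pairs)))
    for s in range(panel.n_subjects):
        for p, (i, j) in enumerate(pairs):
            out[s, p] = ndtw(panel.data[s, i], panel.data[s, j], params)
    return out


def pairwise_ndtw_frame(panel, params: DtwParams):
    """Long-format pair table with 1-based channel indices, ready for CSV export."""
    import pandas as pd

    from .panel import channel_pairs

    mat = pairwise_ndtw(panel, params)
    pairs = channel_pairs(panel.n_channels)
    rows = []
    for s, sid in enumerate(panel.subject_ids):
        for p, (i, j) in enumerate(pairs):
            rows.append((sid, i + 1, j + 1, mat[s, p]))
    return pd.DataFrame(rows, columns=["subject", "pair_i", "pair_j", "ndtw"])
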