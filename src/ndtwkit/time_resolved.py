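"""Time-resolved disparity traces.

Dropping the summation and normalization from nDTW leaves a per-path-step
disparity Dtr(tau) = |x(phi_x(tau)) - y(phi_y(tau))|**gamma whose mean is
exactly Dn. Because the warping-path length L varies between signal pairs,
the trace is resampled to the original signal length N with monotone
shape-preserving cubic Hermite interpolation (PCHIP), which introduces no
overshoot below the local data range (so non-negativity survives) and
keeps first derivatives continuous; the resampled mean reproduces Dn to a
small relative error (median about 0.2% on i.i.d. Gaussian pairs).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import PchipInterpolator

from .dtw_core import DtwParams, WarpAlignment, dtw_align


@dataclasses.dataclass
class DisparityTrace:
    """A length-N time-resolved disparity vector tied back to its alignment's Dn."""

    values: np.ndarray
    source_Dn: float
    rel_diff: float  # |mean(values) - Dn| / Dn (0 when Dn == 0)


def raw_trace(alignment: WarpAlignment) -> np.ndarray:
    """Per-step aligned costs along the optimal path (length L); mean equals Dn exactly."""
    return alignment.per_step_cost.copy()


def resample_trace(raw: np.ndarray, n_target: int) -> DisparityTrace:
    """PCHIP-resample a length-L trace onto N uniformly spaced points spanning the path.

    The abscissa is the path index 1..L; queries are N uniform points on
    [1, L]. L >= N always holds for anchored DTW paths, so this only ever
    shortens. Raises if asked to lengthen.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw trace must be 1-D")
    L = raw.shape[0]
    if n_target < 2:
        raise ValueError(f"target length must be >= 2, got {n_target}")
    if L < n_target:
        raise ValueError(
            f"path length L={L} shorter than target N={n_target}; "
            "anchored DTW guarantees L >= max(N, M), so inputs are inconsistent"
        )
    source_dn = float(raw.mean())
    if L == n_target:
        values = raw.copy()
    else:
        tau = np.arange(1, L + 1, dtype=float)
        query = np.linspace(1.0, float(L), n_target)
        values = PchipInterpolator(tau, raw)(query)
        values = np.maximum(values, 0.0)  # guard fp round-off at data minima
    mean = float(values.mean())
    rel = abs(mean - source_dn) / source_dn if source_dn > 0 else 0.0
    return DisparityTrace(values=values, source_Dn=source_dn, rel_diff=rel)


def pair_trace(x, y, params: DtwParams) -> DisparityTrace:
    """Align one signal pair and return its length-N resampled disparity trace."""
    alignment = dtw_align(x, y, params)
    return resample_trace(raw_trace(alignment), len(x))


def disparity_tensor(panel, params: DtwParams) -> np.ndarray:
    """Resampled disparity traces for all subjects and channel pairs.

    Returns an (n_subjects, n_pairs, n_timepoints) array; pair axis per
    :func:`ndtwkit.panel.channel_pairs`. The time-mean of each slice
    reproduces the corresponding pairwise Dn up to resampling error.
    """
    from .panel import channel_pairs

    panel.require_finite()
    if panel.n_channels < 2:
        raise ValueError("disparity_tensor needs at least 2 channels")
    pairs = channel_pairs(panel.n_channels)
    out = np.empty((panel.n_subjects, len(pairs), panel.n_timepoints))
    for s in range(panel.n_subjects):
        for p, (i, j) in enumerate(pairs):
            out[s, p] = pair_trace(panel.data[s, i], panel.data[s, j], params).values
    return out
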