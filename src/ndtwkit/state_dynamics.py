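"""Recurring-state extraction from disparity tensors.

Timepoints from all subjects are pooled as samples (features = channel
pairs) and clustered with city-block (L1) k-means — centroid updates use
the per-feature median, the L1-optimal center. Anchored DTW biases the
trace near the series ends, so a few edge timepoints are trimmed first.
The number of states is picked from the within-cluster sum-of-distances
(WSS) curve at its elbow, and centroids are re-oriented for display so
positive values mean convergence (low disparity).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.spatial.distance import cdist


@dataclasses.dataclass
class StateModel:
    """Fitted state model: selected k plus the per-k WSS curve behind it."""

    k: int
    centroids: np.ndarray  # (k, n_pairs)
    labels: np.ndarray  # concatenated per-timepoint assignments, values 0..k-1
    wss_curve: dict[int, float]
    elbow_warning: bool = False
    per_k: dict = dataclasses.field(default_factory=dict, repr=False)


def trim_edges(tensor: np.ndarray, trim: int = 5) -> np.ndarray:
    """Drop `trim` timepoints from each end of the time axis (alignment anchoring bias)."""
    tensor = np.asarray(tensor)
    n = tensor.shape[-1]
    if trim < 0:
        raise ValueError("trim must be >= 0")
    if trim == 0:
        return tensor
    if n <= 2 * trim:
        raise ValueError(f"series of {n} timepoints too short to trim {trim} from each end")
    return tensor[..., trim:n - trim]


def _kmedians_once(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=np.int64)
    for it in range(max_iter):
        dist = cdist(X, centers, metric="cityblock")
        new_labels = dist.argmin(axis=1)
        for j in range(k):  # re-seed empty clusters from the worst-fit sample
            if not np.any(new_labels == j):
                far = dist[np.arange(n), new_labels].argmax()
                centers[j] = X[far]
                new_labels[far] = j
        if it > 0 and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = labels == j
            if np.any(members):  # degenerate duplicate-center case keeps old center
                centers[j] = np.median(X[members], axis=0)
    dist = cdist(X, centers, metric="cityblock")
    labels = dist.argmin(axis=1)
    wss = float(dist[np.arange(n), labels].sum())
    return centers, labels, wss


def fit_states(
    tensor: np.ndarray,
    k_range=range(1, 11),
    reps: int = 20,
    max_iter: int = 10000,
    seed: int = 0,
    select_k: bool = True,
) -> StateModel:
    """Best-of-`reps` city-block k-means over pooled timepoints for each candidate k.

    ``tensor`` is (n_subjects, n_pairs, n_timepoints) (or an already-pooled
    2-D samples x features matrix). Deterministic under ``seed``. The
    returned model carries every candidate k's best fit in ``per_k`` and,
    when ``select_k``, the elbow-selected k's centroids and labels.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim == 3:
        X = np.transpose(tensor, (0, 2, 1)).reshape(-1, tensor.shape[1])
    elif tensor.ndim == 2:
        X = tensor
    else:
        raise ValueError("tensor must be 2-D (samples x features) or 3-D (subjects x pairs x time)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in clustering input")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    per_k, wss_curve = {}, {}
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} available samples")
        best = None
        for _ in range(reps):
            fit = _kmedians_once(X, k, rng, max_iter)
            if best is None or fit[2] < best[2]:
                best = fit
        per_k[k] = {"centroids": best[0], "labels": best[1], "wss": best[2]}
        wss_curve[k] = best[2]
    if select_k and len(wss_curve) >= 4:
        k_sel, warn = select_k_elbow(wss_curve)
    else:
        k_sel, warn = max(wss_curve), False
    chosen = per_k[k_sel]
    return StateModel(
        k=k_sel,
        centroids=chosen["centroids"],
        labels=chosen["labels"],
        wss_curve=wss_curve,
        elbow_warning=warn,
        per_k=per_k,
    )


def select_k_elbow(wss_curve) -> tuple[int, bool]:
    """Elbow of the WSS curve: first k where the WSS decrease flattens most abruptly.

    The frozen rule: with Delta(k) = WSS(k) - WSS(k+1), pick
    k* = argmax_k Delta(k-1) / Delta(k) over interior k (first maximum on
    ties) — the point where the preceding drop most dominates the following
    one, i.e. the sharpest bend of the first derivative. A curve with no
    bend (all ratios ~1, e.g. strictly linear WSS) returns the smallest
    interior k with a warning flag.

    Accepts a dict {k: wss} or a sequence (taken as k = 1, 2, ...).
    Returns (k, no_elbow_flag).
    """
    if isinstance(wss_curve, dict):
        ks = sorted(wss_curve)
        wss = np.array([wss_curve[k] for k in ks], dtype=float)
    else:
        wss = np.asarray(wss_curve, dtype=float)
        ks = list(range(1, len(wss) + 1))
    if len(wss) < 4:
        raise ValueError("need a WSS curve over at least 4 candidate k values")
    eps = 1e-12 * max(1.0, float(np.abs(wss).max()))
    delta = -np.diff(wss)  # Delta(k_i) = wss_i - wss_{i+1}
    delta = np.maximum(delta, 0.0)  # WSS is non-increasing up to solver noise
    ratios = delta[:-1] / np.maximum(delta[1:], eps)
    best = int(np.argmax(ratios))  # argmax returns the first maximum on ties
    no_elbow = bool(ratios.max() <= 1.0 + 1e-9)
    if no_elbow:
        warnings.warn("WSS curve has no discernible elbow; returned k is arbitrary", stacklevel=2)
    return ks[best + 1], no_elbow


def orient_states(model: StateModel):
    """Display-oriented centroids and state roles; raw centroids are untouched.

    display = -(centroids - median over all centroid entries), so positive
    display values represent convergence. States are ranked by mean display
    value: highest = "convergent", lowest = "divergent", the rest "mixed"
    (ties broken by state index).

    Returns (display_centroids, roles) with roles a list indexed by state.
    """
    c = model.centroids
    display = -(c - np.median(c))
    means = display.mean(axis=1)
    order = np.lexsort((np.arange(len(means)), -means))  # descending, index tie-break
    roles = ["mixed"] * c.shape[0]
    roles[order[0]] = "convergent"
    roles[order[-1]] = "divergent"
    return display, roles


def state_pair_map(
    display_centroid: np.ndarray, role: str, top_fraction: float = 0.05
) -> np.ndarray:
    """Indices of the strongest pairs in one state's display centroid.

    Convergent and divergent states keep the ceil(fraction * n_pairs)
    strongest pairs of their dominant sign (positive = convergent,
    negative = divergent); a mixed state keeps the union of the top
    fraction/2 most positive and fraction/2 most negative pairs.
    An all-zero centroid yields an empty map with a warning.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    v = np.asarray(display_centroid, dtype=float)
    n = v.shape[0]
    if np.all(v == 0):
        warnings.warn("all-zero display centroid; empty pair map", stacklevel=2)
        return np.array([], dtype=np.int64)
    if role == "convergent":
        count = math.ceil(top_fraction * n)
        order = np.argsort(-v, kind="stable")
        return np.sort(order[:count])
    if role == "divergent":
        count = math.ceil(top_fraction * n)
        order = np.argsort(v, kind="stable")
        return np.sort(order[:count])
    if role == "mixed":
        count = math.ceil(top_fraction / 2.0 * n)
        pos = np.argsort(-v, kind="stable")[:count]
        neg = np.argsort(v, kind="stable")[:count]
        return np.unique(np.concatenate([pos, neg]))
    raise ValueError(f"unknown role {role!r}")


def split_labels(model: StateModel, n_subjects: int, n_timepoints: int) -> np.ndarray:
    """Reshape pooled labels back to (n_subjects, n_timepoints) sequences."""
    if model.labels.size != n_subjects * n_timepoints:
        raise ValueError(
            f"label count {model.labels.size} does not factor as "
            f"{n_subjects} subjects x {n_timepoints} timepoints"
        )
    return model.labels.reshape(n_subjects, n_timepoints)
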