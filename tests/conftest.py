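import numpy as np
import pytest

from ndtwkit.panel import TimeSeriesPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_panel(rng):
    """2 subjects x 3 channels x 120 timepoints of band-limited-ish noise."""
    from scipy import signal as sg

    sos = sg.butter(4, 0.15, btype="lowpass", fs=0.5, output="sos")
    data = sg.sosfiltfilt(sos, rng.standard_normal((2, 3, 120)), axis=-1)
    data = (data - data.mean(axis=-1, keepdims=True)) / data.std(axis=-1, keepdims=True)
    return TimeSeriesPanel(data=data, tr=2.0)


def brute_force_dtw(x, y, gamma, window):
    """Exhaustive enumeration of all monotone anchored warping paths inside the band.

    Independent oracle for small instances (N, M <= ~7): returns
    (min_cost, best_path) over every path from (0, 0) to (N-1, M-1) with
    steps (+1,+1), (+1,0), (0,+1) and |i - j| <= window.
    """
    n, m = len(x), len(y)
    best = {"cost": np.inf, "path": None}

    def step(i, j, cost, path):
        if cost >= best["cost"]:
            return
        if i == n - 1 and j == m - 1:
            best["cost"] = cost
            best["path"] = list(path)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ii, jj = i + di, j + dj
            if ii < n and jj < m and abs(ii - jj) <= window:
                path.append((ii, jj))
                step(ii, jj, cost + abs(x[ii] - y[jj]) ** gamma, path)
                path.pop()

    if abs(n - m) > window:
        raise ValueError("infeasible window")
    start_cost = abs(x[0] - y[0]) ** gamma
    step(0, 0, start_cost, [(0, 0)])
    return best["cost"], best["path"]
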