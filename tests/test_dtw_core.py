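import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndtwkit.dtw_core import DtwParams, dtw_align, gamma_cost, ndtw, pairwise_ndtw
from ndtwkit.panel import TimeSeriesPanel, channel_pairs

from conftest import brute_force_dtw


class TestGammaCost:
    @pytest.mark.parametrize(
        "a,b,gamma,expected",
        [(3, 1, 2, 4), (5, 5, 1.7, 0), (0, 2, 0.5, np.sqrt(2)), (1, -1, 1, 2)],
    )
    def test_closed_form(self, a, b, gamma, expected):
        assert gamma_cost(a, b, gamma) == pytest.approx(expected)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            gamma_cost(1, 2, 0)


class TestDtwAlign:
    def test_identity_alignment_is_diagonal(self, rng):
        x = rng.standard_normal(30)
        a = dtw_align(x, x, DtwParams(gamma=1.5, window=5))
        assert a.D == 0
        assert a.L == 30
        assert np.array_equal(a.path[:, 0], a.path[:, 1])

    def test_alignment_invariants(self, rng):
        """Path anchored, monotone with unit steps, inside the band; D = sum of step costs."""
        x, y = rng.standard_normal(40), rng.standard_normal(37)
        a = dtw_align(x, y, DtwParams(gamma=1.5, window=6))
        assert tuple(a.path[0]) == (0, 0)
        assert tuple(a.path[-1]) == (39, 36)
        steps = np.diff(a.path, axis=0)
        assert set(map(tuple, steps)) <= {(1, 1), (1, 0), (0, 1)}
        assert np.all(np.abs(a.path[:, 0] - a.path[:, 1]) <= 6)
        assert a.L >= 40
        assert a.D == pytest.approx(a.per_step_cost.sum())
        assert a.Dn == pytest.approx(a.D / a.L)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.5, 2.0])
    def test_matches_exhaustive_enumeration(self, gamma):
        """DP distance equals the brute-force minimum over all banded monotone paths."""
        rng = np.random.default_rng(1234)
        for _ in range(60):
            n, m = rng.integers(2, 7, size=2)
            w = int(rng.integers(max(1, abs(n - m)), 7))
            x, y = rng.standard_normal(n), rng.standard_normal(m)
            expected, _ = brute_force_dtw(x, y, gamma, w)
            a = dtw_align(x, y, DtwParams(gamma=gamma, window=w))
            assert a.D == pytest.approx(expected, abs=1e-12)
            assert a.per_step_cost.sum() == pytest.approx(expected, abs=1e-12)

    def test_small_example_against_oracle(self):
        x, y = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0, 0.0])
        expected, _ = brute_force_dtw(x, y, 1.0, 2)
        a = dtw_align(x, y, DtwParams(gamma=1.0, window=2))
        assert a.D == pytest.approx(expected)

    def test_window_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            dtw_align(np.zeros(10), np.zeros(20), DtwParams(window=3))

    def test_nonfinite_input(self):
        x = np.array([0.0, np.nan, 1.0])
        with pytest.raises(ValueError, match="non-finite"):
            dtw_align(x, np.zeros(3), DtwParams(window=2))

    def test_window_zero_rejected(self):
        with pytest.raises(ValueError, match="window"):
            DtwParams(window=0)

    def test_distance_bounded_by_diagonal_cost(self, rng):
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        diag = np.sum((x - y) ** 2)
        for w in (1, 10, 100):
            a = dtw_align(x, y, DtwParams(gamma=2.0, window=w))
            assert a.D <= diag + 1e-12

    def test_distance_nonincreasing_in_window(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        costs = [dtw_align(x, y, DtwParams(gamma=1.5, window=w)).D for w in (1, 2, 5, 10, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_deterministic_ties(self):
        # piecewise-constant series create massive cost ties; same input must
        # always return the identical path under the fixed tie-break rule
        x = np.repeat([0.0, 1.0], 5)
        y = np.repeat([0.0, 1.0], 5)
        p1 = dtw_align(x, y, DtwParams(window=4)).path
        p2 = dtw_align(x, y, DtwParams(window=4)).path
        assert np.array_equal(p1, p2)


class TestNdtw:
    def test_symmetry_and_identity(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        params = DtwParams(gamma=1.5, window=5)
        assert ndtw(x, x, params) == 0
        assert ndtw(x, y, params) == pytest.approx(ndtw(y, x, params))

    def test_two_point_example(self):
        # brute force by hand: only path is the diagonal of length 2
        assert ndtw(np.array([0.0, 0.0]), np.array([1.0, 1.0]), DtwParams(gamma=1, window=1)) == 1.0

    def test_phase_shift_tolerated(self):
        """A within-window time shift costs almost nothing; without alignment it would not."""
        t = np.arange(1200) * 2.0
        x = np.sin(2 * np.pi * 0.02 * t)
        y = np.sin(2 * np.pi * 0.02 * (t - 8.0))  # 4-sample lag, well inside w
        params = DtwParams(gamma=1.5, window=45)
        shifted = ndtw(x, y, params)
        unshifted_cost = np.mean(np.abs(x - y) ** 1.5)
        assert shifted <= 0.01 * unshifted_cost


class TestPairwise:
    def test_identical_channels_zero(self):
        data = np.tile(np.sin(np.linspace(0, 6, 50)), (1, 3, 1)).reshape(1, 3, 50)
        panel = TimeSeriesPanel(data=data, tr=2.0)
        out = pairwise_ndtw(panel, DtwParams(window=5))
        assert out.shape == (1, 3)
        assert np.all(out == 0)

    def test_scaled_channel_has_larger_disparity(self, rng):
        base = np.sin(np.linspace(0, 12, 80))
        data = np.stack([base, base, 2 * base])[None]
        panel = TimeSeriesPanel(data=data, tr=2.0)
        out = pairwise_ndtw(panel, DtwParams(gamma=1.5, window=5))[0]
        pairs = channel_pairs(3)
        identical = out[pairs.index((0, 1))]
        assert out[pairs.index((0, 2))] > identical
        assert out[pairs.index((1, 2))] > identical

    def test_matches_looped_single_calls(self, small_panel):
        params = DtwParams(gamma=1.5, window=8)
        mat = pairwise_ndtw(small_panel, params)
        for s in range(small_panel.n_subjects):
            for p, (i, j) in enumerate(channel_pairs(small_panel.n_channels)):
                assert mat[s, p] == ndtw(small_panel.data[s, i], small_panel.data[s, j], params)


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=4, max_size=12
    ),
    gamma=st.sampled_from([0.5, 1.0, 1.5, 2.0]),
)
def test_property_self_distance_and_nonnegativity(data, gamma):
    x = np.asarray(data)
    a = dtw_align(x, x, DtwParams(gamma=gamma, window=3))
    assert a.D == 0
    y = x[::-1].copy()
    b = dtw_align(x, y, DtwParams(gamma=gamma, window=len(x)))
    assert b.D >= 0
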