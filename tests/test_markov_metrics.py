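import numpy as np
import pytest

from ndtwkit import markov_metrics as mm


def random_ergodic(rng, k=3):
    """Strictly positive row-stochastic matrix (hence ergodic)."""
    P = rng.dirichlet(np.ones(k) * 2, size=k) + 0.01
    return P / P.sum(axis=1, keepdims=True)


def symmetric_three_state(p):
    return np.full((3, 3), p) + (1 - 3 * p) * np.eye(3)


class TestTransitionMatrix:
    def test_hand_count(self):
        tm = mm.transition_matrix(np.array([0, 0, 1, 1, 1, 0]), k=3)
        assert tm.counts.tolist() == [[1, 1, 0], [1, 2, 0], [0, 0, 0]]
        assert np.allclose(tm.P[0], [0.5, 0.5, 0.0])
        assert np.allclose(tm.P[1], [1 / 3, 2 / 3, 0.0])
        assert np.all(tm.P[2] == 0)  # never-visited row stays zero

    def test_constant_sequence(self):
        tm = mm.transition_matrix(np.zeros(10, dtype=int), k=2)
        assert tm.P[0, 0] == 1.0
        assert not mm.is_ergodic(tm.P)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mm.transition_matrix(np.array([0]), k=2)

    def test_aggregate_is_count_weighted(self, rng):
        seqs = [rng.integers(0, 3, 50) for _ in range(4)]
        tms = [mm.transition_matrix(s, 3) for s in seqs]
        agg = mm.aggregate_transition_matrix(tms)
        total = np.sum([tm.counts for tm in tms], axis=0)
        assert np.array_equal(agg.counts, total)
        assert np.allclose(agg.P, total / total.sum(axis=1, keepdims=True))


class TestErgodicity:
    def test_strictly_positive_is_ergodic(self, rng):
        assert mm.is_ergodic(random_ergodic(rng))

    def test_deterministic_swap_is_periodic(self):
        assert not mm.is_ergodic(np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_block_disconnected(self):
        P = np.array(
            [[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5], [0, 0, 0.5, 0.5]]
        )
        assert not mm.is_ergodic(P)


class TestStationary:
    def test_symmetric_two_state(self):
        pi = mm.stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert np.allclose(pi, [0.5, 0.5])

    def test_defining_identity_on_random_chains(self, rng):
        for _ in range(50):
            P = random_ergodic(rng)
            pi = mm.stationary_distribution(P)
            assert np.abs(pi @ P - pi).max() < 1e-12
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert pi.min() >= 0

    def test_agrees_with_power_iteration(self, rng):
        P = random_ergodic(rng)
        pi = mm.stationary_distribution(P)
        mu = np.full(3, 1 / 3)
        for _ in range(10000):
            mu = mu @ P
        assert np.abs(mu - pi).max() < 1e-10

    def test_non_ergodic_rejected(self):
        with pytest.raises(ValueError, match="ergodic"):
            mm.stationary_distribution(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestSpectralGap:
    @pytest.mark.parametrize("p", [0.01, 0.05, 0.1, 0.2, 0.3])
    def test_symmetric_family_closed_form(self, p):
        # eigenvalues of p(J - I) + (1 - 3p) I are 1 and 1 - 3p (twice)
        assert mm.spectral_gap(symmetric_three_state(p)) == pytest.approx(3 * p, abs=1e-12)

    def test_two_state_closed_form(self):
        assert mm.spectral_gap(np.array([[0.9, 0.1], [0.1, 0.9]])) == pytest.approx(0.2)


class TestMixingTime:
    def test_stationary_start_needs_no_steps(self, rng):
        P = random_ergodic(rng)
        pi = mm.stationary_distribution(P)
        assert mm.mixing_time(P, pi, mu0=pi) == 0

    @pytest.mark.parametrize("tol", [1e-2, 1e-3, 1e-4])
    def test_two_state_analytic_decay(self, tol):
        # from [1, 0]: TV after t steps is 0.5 * (1 - 2p)^t
        p = 0.1
        P = np.array([[1 - p, p], [p, 1 - p]])
        pi = np.array([0.5, 0.5])
        expected = int(np.ceil(np.log(2 * tol) / np.log(1 - 2 * p)))
        assert mm.mixing_time(P, pi, mu0=np.array([1.0, 0.0]), tol=tol) == expected

    def test_default_start_is_least_probable_vertex(self):
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        pi = mm.stationary_distribution(P)
        vertex = mm.farthest_vertex(pi)
        assert vertex[np.argmin(pi)] == 1.0
        # TV from a vertex is 1 - pi of that state, maximal at the smallest pi
        assert mm.total_variation(vertex, pi) == pytest.approx(1 - pi.min())

    def test_nonconvergence_raises(self):
        P = np.array([[0.999999, 0.000001], [0.000001, 0.999999]])
        with pytest.raises(RuntimeError, match="did not reach"):
            mm.mixing_time(P, tol=1e-9, max_steps=10)


class TestEntropyRate:
    def test_uniform_three_state_is_maximal(self):
        H, pct = mm.entropy_rate(np.full((3, 3), 1 / 3))
        assert H == pytest.approx(np.log2(3))
        assert H == pytest.approx(1.585, abs=5e-4)
        assert pct == pytest.approx(100.0)

    def test_deterministic_cycle_zero(self):
        P = np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]])
        pi = np.full(3, 1 / 3)
        H, pct = mm.entropy_rate(P, pi)
        assert H == 0 and pct == 0

    def test_two_state_binary_entropy(self):
        H, _ = mm.entropy_rate(np.array([[0.9, 0.1], [0.1, 0.9]]))
        expected = -(0.9 * np.log2(0.9) + 0.1 * np.log2(0.1))
        assert H == pytest.approx(expected)
        assert H == pytest.approx(0.4690, abs=5e-5)

    def test_percentage_bounds(self, rng):
        for _ in range(20):
            _, pct = mm.entropy_rate(random_ergodic(rng))
            assert 0 <= pct <= 100


class TestDwellOccupancy:
    def test_hand_example(self):
        occ = mm.dwell_occupancy(np.array([0, 0, 1, 1, 1, 0]), k=3)
        assert occ.mean_dwell[0] == pytest.approx(1.5)
        assert occ.mean_dwell[1] == pytest.approx(3.0)
        assert np.isnan(occ.mean_dwell[2])
        assert np.allclose(occ.occupancy, [50.0, 50.0, 0.0])

    def test_constant_sequence(self):
        occ = mm.dwell_occupancy(np.zeros(40, dtype=int), k=2)
        assert occ.mean_dwell[0] == 40
        assert occ.occupancy[0] == 100.0

    def test_alternating(self):
        occ = mm.dwell_occupancy(np.array([0, 1, 0, 1, 0, 1]), k=2)
        assert occ.mean_dwell[0] == 1.0 and occ.mean_dwell[1] == 1.0

    def test_occupancy_sums_to_hundred(self, rng):
        occ = mm.dwell_occupancy(rng.integers(0, 4, 200), k=4)
        assert occ.occupancy.sum() == pytest.approx(100.0)


class TestPerturbation:
    def test_zero_magnitude_limit(self, rng):
        P = symmetric_three_state(0.1)
        out = mm.perturb_transitions(
            P, n_samples=5, magnitude_range=(1e-12, 2e-12), seed=0
        )
        assert np.abs(out["spectral_gap_pct"]).max() < 1e-6
        assert np.abs(out["entropy_rate_pct"]).max() < 1e-6

    def test_self_retention_reduces_gap(self):
        """Boosting any diagonal cell slows convergence on the symmetric chain."""
        P = symmetric_three_state(0.1)
        out = mm.perturb_transitions(P, n_samples=50, seed=1)
        diag = np.diagonal(out["spectral_gap_pct"])
        assert np.all(diag < 0)

    def test_seed_determinism(self):
        P = symmetric_three_state(0.15)
        a = mm.perturb_transitions(P, n_samples=20, seed=3)
        b = mm.perturb_transitions(P, n_samples=20, seed=3)
        assert np.array_equal(a["magnitudes"], b["magnitudes"])
        assert np.allclose(a["spectral_gap_pct"], b["spectral_gap_pct"])

    def test_exclusion_mask(self):
        P = symmetric_three_state(0.1)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 2] = True
        out = mm.perturb_transitions(P, n_samples=5, seed=0, exclude=mask)
        assert np.isnan(out["spectral_gap_pct"][0, 2])
        assert np.isfinite(out["spectral_gap_pct"][1, 1])


class TestCohortChainRecovery:
    def test_aggregate_recovers_planted_chain(self):
        """Sampling paths from a known chain and re-estimating stays within 3 SE."""
        rng = np.random.default_rng(8)
        P = np.array([[0.9, 0.08, 0.02], [0.06, 0.88, 0.06], [0.02, 0.08, 0.9]])
        pi = mm.stationary_distribution(P)
        tms = []
        for _ in range(12):
            seq = np.empty(300, dtype=int)
            seq[0] = rng.choice(3, p=pi)
            for t in range(1, 300):
                seq[t] = rng.choice(3, p=P[seq[t - 1]])
            tms.append(mm.transition_matrix(seq, 3))
        agg = mm.aggregate_transition_matrix(tms)
        row_n = agg.counts.sum(axis=1, keepdims=True)
        se = np.sqrt(P * (1 - P) / row_n)
        assert np.all(np.abs(agg.P - P) <= 3 * se)
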