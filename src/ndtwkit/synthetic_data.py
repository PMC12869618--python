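"""Synthetic BOLD-like signal and cohort generators.

Three families of inputs exercise the whole pipeline without real scans:

* modulated sinusoid pairs — amplitude modulation creates amplitude
  disparity (which nDTW should track) while phase modulation creates
  timing misalignment (which nDTW should tolerate and correlation should
  not);
* band-limited Gaussian noise — bandwidth controls signal roughness and
  hence how much disparity alignment can absorb;
* planted-state cohorts — each subject follows a hidden ergodic Markov
  chain over convergent / mixed / divergent states; channel pairs emit
  amplitude imbalance consistent with the active state, confounded by
  bounded random time warps of a shared slow carrier, so the planted
  structure is recoverable only by a timing-invariant amplitude metric.

Every generator routes all randomness through one seeded Generator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sg

from .panel import TimeSeriesPanel


@dataclasses.dataclass(frozen=True)
class ModulationSpec:
    """Amplitude/phase-modulated sinusoid pair configuration.

    y(t) = (1 + a * depth * m(t)) sin(2 pi f t + phi p(t)) against the
    clean base x(t) = sin(2 pi f t), with slow unit sinusoidal modulators
    m, p at ``mod_freq``. The amplitude index a scales a shallow envelope
    drift (``mod_depth`` fractional swing per unit index, so the index
    grid 0..1 spans gentle nonstationarity rather than full fading); the
    phase index phi is the peak phase excursion in radians. Both default
    to 0 (y == x).
    """

    base_freq: float = 0.02  # Hz, slow BOLD-band fluctuation
    amp_mod_index: float = 0.0
    phase_mod_index: float = 0.0
    mod_depth: float = 0.15  # envelope swing per unit amplitude index
    mod_freq: float = 0.005  # Hz, slow nonstationary drift of the modulators
    duration: float = 600.0  # s
    fs: float = 0.5  # Hz (TR = 2 s)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 2 * self.base_freq:
            raise ValueError("fs must exceed twice the base frequency")
        if self.amp_mod_index < 0 or self.phase_mod_index < 0:
            raise ValueError("modulation indices must be >= 0")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Planted-state cohort configuration.

    Channels come in groups of two. All channels of a subject ride one
    slow band-limited carrier, each through its own bounded random time
    warp (so every pair is timing-confounded); the second channel of each
    group additionally carries a state-dependent fast amplitude imbalance
    m * (-1)^t whose magnitude m follows the hidden state path. The fast
    alternation makes the planted imbalance irreducible by alignment —
    every sample of the partner must be visited, and the slow carrier
    cannot bridge the offset inside a small window — so the disparity
    schedule is recoverable only through a timing-invariant amplitude
    metric, not through correlation of the raw series.

    ``state_levels`` maps each state to per-group imbalance magnitudes;
    rows of ``transition`` must form an ergodic chain.
    """

    n_subjects: int = 10
    n_channels: int = 8  # must be even: channels pair up into groups
    n_timepoints: int = 160
    tr: float = 2.0
    transition: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array(
            [[0.96, 0.03, 0.01], [0.03, 0.94, 0.03], [0.01, 0.03, 0.96]]
        )
    )
    # per-state imbalance magnitude per channel group: convergent low
    # everywhere, mixed high on half the groups, divergent high everywhere
    state_levels: np.ndarray | None = None
    noise_sd: float = 0.02
    max_warp: int = 1  # samples; the DTW window must cover it
    carrier_fraction: float = 0.05  # carrier bandwidth as a fraction of Nyquist
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels % 2:
            raise ValueError("n_channels must be even (channels pair into groups)")
        P = np.asarray(self.transition, dtype=float)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9) or np.any(P < 0):
            raise ValueError("planted transition matrix must be row-stochastic")
        from .markov_metrics import is_ergodic

        if not is_ergodic(P):
            raise ValueError("planted transition matrix must be ergodic")

    @property
    def n_states(self) -> int:
        return np.asarray(self.transition).shape[0]

    @property
    def n_groups(self) -> int:
        return self.n_channels // 2

    def levels(self) -> np.ndarray:
        """(n_states, n_groups) imbalance magnitudes; default low/half/high pattern."""
        if self.state_levels is not None:
            lv = np.asarray(self.state_levels, dtype=float)
            if lv.shape != (self.n_states, self.n_groups):
                raise ValueError("state_levels must be (n_states, n_groups)")
            return lv
        low, mid, high = 0.05, 0.7, 1.0
        lv = np.full((3, self.n_groups), low)
        half = self.n_groups // 2 if self.n_groups > 1 else 1
        lv[1, :half] = mid  # mixed: elevated on half the groups
        lv[2, :] = high  # divergent: high everywhere
        return lv


def gen_modulated_pair(spec: ModulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """A base sinusoid and its amplitude/phase-modulated counterpart."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(spec.seed)
    # random modulator phases make repeated draws distinct but seeded
    pm_a, pm_p = rng.uniform(0, 2 * np.pi, size=2)
    m = np.sin(2 * np.pi * spec.mod_freq * t + pm_a)
    p = np.sin(2 * np.pi * spec.mod_freq * t + pm_p)
    x = np.sin(2 * np.pi * spec.base_freq * t)
    y = (1.0 + spec.amp_mod_index * spec.mod_depth * m) * np.sin(
        2 * np.pi * spec.base_freq * t + spec.phase_mod_index * p
    )
    return x, y


def gen_band_limited_noise(
    bandwidth_fraction: float, n: int, fs: float = 0.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to a fraction of Nyquist.

    ``bandwidth_fraction`` = 1 returns (standardized) white noise; smaller
    fractions give progressively smoother series.
    """
    if not 0 < bandwidth_fraction <= 1:
        raise ValueError("bandwidth_fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    if bandwidth_fraction < 1:
        nyq = fs / 2.0
        sos = sg.butter(8, bandwidth_fraction * nyq, btype="lowpass", fs=fs, output="sos")
        z = sg.sosfiltfilt(sos, z)
    sd = z.std()
    if sd == 0:
        raise RuntimeError("degenerate all-zero noise draw")
    return (z - z.mean()) / sd


def gen_gaussian_pairs(
    n_pairs: int = 10000, length: int = 150, seed: int = 0
) -> np.ndarray:
    """I.i.d. standard-normal signal pairs, shape (n_pairs, 2, length)."""
    if n_pairs < 1 or length < 2:
        raise ValueError("need n_pairs >= 1 and length >= 2")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_pairs, 2, length))


def _bounded_warp(x: np.ndarray, max_warp: int, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Resample a series along a smooth random time distortion of bounded amplitude."""
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    jitter = gen_band_limited_noise(0.1, n, fs=1.0, seed=rng)
    jitter = jitter / max(np.abs(jitter).max(), 1e-12) * max_warp
    return np.interp(np.clip(t + jitter, 0, n - 1), t, x)


def _gen_group_panel(
    spec: CohortSpec, n_subjects: int, transition: np.ndarray, rng: np.random.Generator
):
    """One group's panel plus its hidden state paths."""
    from .markov_metrics import stationary_distribution

    P = np.asarray(transition, dtype=float)
    k = P.shape[0]
    pi = stationary_distribution(P)
    lv = spec.levels()
    n, fs = spec.n_timepoints, 1.0 / spec.tr
    # the fast imbalance component alternates sign every sample (content at
    # the Nyquist edge), so alignment cannot phase-shift it away
    alternation = np.cos(np.pi * np.arange(n))
    data = np.empty((n_subjects, spec.n_channels, n))
    paths = np.empty((n_subjects, n), dtype=np.int64)
    for s in range(n_subjects):
        # hidden state path from the planted chain
        states = np.empty(n, dtype=np.int64)
        states[0] = rng.choice(k, p=pi)
        for t in range(1, n):
            states[t] = rng.choice(k, p=P[states[t - 1]])
        paths[s] = states
        # one slow carrier per subject: a global BOLD-like fluctuation all
        # channels follow, so cross-group pairs are informative too
        carrier = gen_band_limited_noise(spec.carrier_fraction, n, fs=fs, seed=rng)
        for g in range(spec.n_groups):
            m = lv[states, g]
            ref = _bounded_warp(carrier, spec.max_warp, rng, fs)
            partner = _bounded_warp(carrier, spec.max_warp, rng, fs) + m * alternation
            data[s, 2 * g] = ref + spec.noise_sd * rng.standard_normal(n)
            data[s, 2 * g + 1] = partner + spec.noise_sd * rng.standard_normal(n)
    panel = TimeSeriesPanel(data=data, tr=spec.tr, band="raw")
    return panel, paths


def gen_cohort(spec: CohortSpec, group2_transition: np.ndarray | None = None):
    """Two groups of subjects with planted state dynamics.

    Group 1 follows ``spec.transition``; group 2 follows
    ``group2_transition`` when given (e.g. elevated divergent
    self-retention for a patient-like group), otherwise the same chain.

    Returns (panel_group1, panel_group2, ground_truth) where ground_truth
    holds the hidden state paths, planted transition matrices and emission
    levels needed to compute every downstream metric in closed form.
    """
    rng = np.random.default_rng(spec.seed)
    P2 = spec.transition if group2_transition is None else np.asarray(group2_transition, float)
    if group2_transition is not None:
        from .markov_metrics import is_ergodic

        if not is_ergodic(P2):
            raise ValueError("group-2 planted transition matrix must be ergodic")
    panel1, paths1 = _gen_group_panel(spec, spec.n_subjects, spec.transition, rng)
    panel2, paths2 = _gen_group_panel(spec, spec.n_subjects, P2, rng)
    ground_truth = {
        "states_group1": paths1,
        "states_group2": paths2,
        "transition_group1": np.asarray(spec.transition, dtype=float),
        "transition_group2": np.asarray(P2, dtype=float),
        "state_levels": spec.levels(),
    }
    return panel1, panel2, ground_truth
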