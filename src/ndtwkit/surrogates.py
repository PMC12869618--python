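"""Phase-randomization surrogate null models.

Phase randomization adds a single random phase sequence to the Fourier
spectra of ALL channels of a subject, which preserves every channel's
amplitude spectrum and all cross-spectra — hence the full linear
correlation structure — while destroying phase-dependent (non-stationary,
higher-order) temporal structure. The band-residual scheme confines the
randomization to the fast residual band (e.g. 0.15-0.198 Hz): the
broad-band (F1) data are phase-randomized, the slow (F2) content of the
randomized data is removed by the same filter that produced the original
F2 data, and the resulting fast residual is added back onto the original
F2 data. An explicit high-pass is avoided because a non-ideal filter would
ring at the band edge.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .panel import TimeSeriesPanel
from .signal_prep import BandpassSpec, apply_zero_phase


@dataclasses.dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate-ensemble configuration."""

    n_surrogates: int = 1000
    seed: int = 0
    mode: str = "band_residual"  # or "full_band"
    base_band: tuple[float, float] = (0.01, 0.15)
    residual_band: tuple[float, float] = (0.15, 0.198)

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.mode not in ("band_residual", "full_band"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.residual_band[0] < self.base_band[1]:
            raise ValueError("residual band must start at or above the base band's upper edge")


def phase_randomize(
    panel: TimeSeriesPanel,
    seed: int | np.random.Generator = 0,
    shared_phases: bool = True,
) -> TimeSeriesPanel:
    """One phase-randomized surrogate of every subject in the panel.

    With ``shared_phases`` (the default) one random phase sequence per
    subject is added to all channels identically, preserving cross-spectra
    and therefore the Pearson correlation matrix exactly; set it False for
    independent per-channel phases (diagnostic use only). DC and Nyquist
    bins get zero added phase so the output stays real.
    """
    panel.require_finite()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = panel.n_timepoints
    n_bins = n // 2 + 1  # rfft bins
    out = np.empty_like(panel.data)
    for s in range(panel.n_subjects):
        if shared_phases:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_bins)
            phases = phases[None, :].repeat(panel.n_channels, axis=0)
        else:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=(panel.n_channels, n_bins))
        phases[:, 0] = 0.0  # DC stays real
        if n % 2 == 0:
            phases[:, -1] = 0.0  # Nyquist bin stays real
        spec = np.fft.rfft(panel.data[s], axis=-1)
        out[s] = np.fft.irfft(spec * np.exp(1j * phases), n=n, axis=-1)
    return panel.with_data(out)


def band_residual_surrogate(
    panel_f1: TimeSeriesPanel,
    panel_f2: TimeSeriesPanel,
    bandpass_f2: BandpassSpec,
    spec: SurrogateSpec,
) -> list[TimeSeriesPanel]:
    """Surrogates whose randomization touches only the residual fast band.

    Steps, per surrogate: Z = phase_randomize(F1 panel); Y = zero-phase
    F2-filter of Z; X = Z - Y (the randomized fast residual); surrogate =
    X + original F2 panel. Reproducible under ``spec.seed``.
    """
    if panel_f1.data.shape != panel_f2.data.shape:
        raise ValueError(
            f"F1 and F2 panels disagree in shape: {panel_f1.data.shape} vs {panel_f2.data.shape}"
        )
    if abs(panel_f1.tr - panel_f2.tr) > 1e-12:
        raise ValueError("F1 and F2 panels have different TR")
    rng = np.random.default_rng(spec.seed)
    surrogates = []
    for _ in range(spec.n_surrogates):
        z = phase_randomize(panel_f1, rng)
        y = apply_zero_phase(z, bandpass_f2)
        x = z.data - y.data
        surrogates.append(panel_f2.with_data(panel_f2.data + x, band=panel_f1.band))
    return surrogates


def surrogate_null_test(
    observed: np.ndarray,
    surrogate_stats: np.ndarray,
    alternative: str = "two-sided",
    alpha: float = 0.05,
):
    """Per-pair comparison of observed statistics against a surrogate null.

    ``surrogate_stats`` is (n_surrogates, n_pairs). Two input shapes for
    ``observed`` are supported:

    * 1-D (n_pairs,) — one observed value per pair: the empirical
      surrogate-rank p-value (1 + #{surrogates at least as extreme}) /
      (n_surrogates + 1), the standard Monte-Carlo null test.
    * 2-D (n_replicates, n_pairs) — an observed distribution per pair:
      Wilcoxon rank-sum test of observed vs surrogate values.

    Returns (p_raw, p_adj, reject) with Benjamini-Hochberg adjustment
    across pairs at level ``alpha``.
    """
    surrogate_stats = np.atleast_2d(np.asarray(surrogate_stats, dtype=float))
    observed = np.asarray(observed, dtype=float)
    n_surr, n_pairs = surrogate_stats.shape
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if observed.ndim == 1:
        if observed.shape[0] != n_pairs:
            raise ValueError("observed length must match the surrogate pair axis")
        ge = (surrogate_stats >= observed[None, :]).sum(axis=0)
        le = (surrogate_stats <= observed[None, :]).sum(axis=0)
        p_greater = (1.0 + ge) / (n_surr + 1.0)
        p_less = (1.0 + le) / (n_surr + 1.0)
        if alternative == "greater":
            p_raw = p_greater
        elif alternative == "less":
            p_raw = p_less
        else:
            p_raw = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    elif observed.ndim == 2:
        if observed.shape[1] != n_pairs:
            raise ValueError("observed pair axis must match the surrogate pair axis")
        p_raw = np.array(
            [
                ranksums(observed[:, p], surrogate_stats[:, p], alternative=alternative).pvalue
                for p in range(n_pairs)
            ]
        )
    else:
        raise ValueError("observed must be 1-D or 2-D")
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return p_raw, p_adj, reject
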