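"""Band-pass filtering, z-scoring, and the DTW window rule.

BOLD network time courses are band-pass filtered (e.g. F1 = 0.01-0.198 Hz
or F2 = 0.01-0.15 Hz) with a minimum-order Butterworth filter applied
forward-backward so phase is preserved, then z-scored per channel. The
DTW window constraint is tied to the filter's low-frequency -3 dB point:
the slowest surviving fluctuation sets how much warping is physiologically
meaningful, via

    f3db = 0.88 / ((N/2 - 1) * TR)

solved for the window length N (samples); the Sakoe-Chiba half-width is
w = round(N/2). At f3db = 0.01 Hz and TR = 2 s this gives N = 90 samples
(180 s), comfortably above the ideal-filter bound of 100 s (one full
wavelength of the 0.01 Hz component: two 50-s half-wavelength shifts, one
per warping direction, being what maximal anti-correlation requires).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal

from .panel import TimeSeriesPanel, RAW_BAND


@dataclasses.dataclass(frozen=True)
class BandpassSpec:
    """A designed minimum-order Butterworth band-pass, serializable for reproducibility."""

    f_lo: float
    f_hi: float
    stop_lo: float
    stop_hi: float
    tr: float
    order: int
    wn_lo: float  # natural frequencies returned by the order selection (Hz)
    wn_hi: float
    passband_ripple_db: float = 3.0
    stopband_atten_db: float = 30.0
    family: str = "butterworth"

    def sos(self) -> np.ndarray:
        """Second-order-sections realization of the designed filter."""
        fs = 1.0 / self.tr
        return signal.butter(
            self.order, [self.wn_lo, self.wn_hi], btype="bandpass", fs=fs, output="sos"
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BandpassSpec":
        return cls(**d)


def design_bandpass(
    f_lo: float,
    f_hi: float,
    tr: float,
    stop_margins: tuple[float, float] | None = None,
    passband_ripple_db: float = 3.0,
    stopband_atten_db: float = 30.0,
) -> BandpassSpec:
    """Minimum-order Butterworth band-pass with <= `passband_ripple_db` dB ripple
    in the passband and >= `stopband_atten_db` dB attenuation in the stopband.

    Stopband edges default to (f_lo/2, min(f_hi + 0.05 Hz, 0.98*Nyquist));
    pass explicit ``stop_margins=(stop_lo, stop_hi)`` to override.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    nyq = 1.0 / (2.0 * tr)
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= nyq:
        raise ValueError(f"band edge f_hi={f_hi} Hz at or above Nyquist {nyq} Hz")
    if stop_margins is None:
        stop_lo = f_lo / 2.0
        stop_hi = min(f_hi + 0.05, 0.98 * nyq)
    else:
        stop_lo, stop_hi = stop_margins
    if not (0 < stop_lo < f_lo and f_hi < stop_hi < nyq):
        raise ValueError(
            f"stopband edges ({stop_lo}, {stop_hi}) must bracket the passband inside (0, Nyquist)"
        )
    fs = 1.0 / tr
    order, wn = signal.buttord(
        [f_lo, f_hi], [stop_lo, stop_hi], passband_ripple_db, stopband_atten_db, fs=fs
    )
    return BandpassSpec(
        f_lo=float(f_lo),
        f_hi=float(f_hi),
        stop_lo=float(stop_lo),
        stop_hi=float(stop_hi),
        tr=float(tr),
        order=int(order),
        wn_lo=float(wn[0]),
        wn_hi=float(wn[1]),
        passband_ripple_db=float(passband_ripple_db),
        stopband_atten_db=float(stopband_atten_db),
    )


def apply_zero_phase(panel: TimeSeriesPanel, spec: BandpassSpec) -> TimeSeriesPanel:
    """Forward-backward (zero-phase) filtering of every channel of every subject.

    Two-pass application doubles the effective attenuation and cancels the
    filter's phase response, so in-band components keep their timing.
    """
    if abs(panel.tr - spec.tr) > 1e-12:
        raise ValueError(f"panel TR {panel.tr} differs from filter design TR {spec.tr}")
    panel.require_finite()
    sos = spec.sos()
    # sosfiltfilt needs > 3 * (padlen) samples; compute its default padding
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if panel.n_timepoints <= padlen:
        raise ValueError(
            f"series of {panel.n_timepoints} samples too short for zero-phase "
            f"filtering (needs > {padlen} for warm-up padding)"
        )
    out = signal.sosfiltfilt(sos, panel.data, axis=-1)
    return panel.with_data(out, band=(spec.f_lo, spec.f_hi))


def zscore(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Per-subject, per-channel standardization to mean 0, sd 1 over time."""
    panel.require_finite()
    mu = panel.data.mean(axis=-1, keepdims=True)
    sd = panel.data.std(axis=-1, keepdims=True)
    zero = np.nonzero(sd[:, :, 0] == 0)
    if zero[0].size:
        s, c = zero[0][0], zero[1][0]
        raise ValueError(
            f"zero-variance channel: subject {panel.subject_ids[s]}, "
            f"channel {panel.channel_labels[c]} is constant"
        )
    return panel.with_data((panel.data - mu) / sd)


def dtw_window_from_cutoff(f3db: float, tr: float) -> int:
    """Sakoe-Chiba half-width w (samples) from the filter's low -3 dB point.

    Solves f3db = 0.88 / ((N/2 - 1)*TR) for the window length N and returns
    w = round(N/2). Decreasing in both f3db and TR; clamped to w >= 1 (with
    a warning) when the cutoff is at or above Nyquist or otherwise degenerate.
    """
    if f3db <= 0:
        raise ValueError(f"f3db must be positive, got {f3db}")
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    nyq = 1.0 / (2.0 * tr)
    n_window = 2.0 * (0.88 / (f3db * tr) + 1.0)
    w = int(round(n_window / 2.0))
    if f3db >= nyq or w < 1:
        warnings.warn(
            f"degenerate low cutoff f3db={f3db} Hz (Nyquist {nyq} Hz); window clamped to 1",
            stacklevel=2,
        )
        w = max(w, 1)
    return w


def ideal_window_bound_seconds(f_lo: float) -> tuple[float, float]:
    """Ideal-filter reasoning behind the window rule, in seconds.

    Returns (wavelength, half_wavelength_shift): the longest wavelength at
    the low cutoff (1/f_lo, 100 s at 0.01 Hz) and the time shift producing
    maximal anti-correlation of -1 (half of it, 50 s). Two such half-wave
    shifts — one per warping direction — motivate a total window of one
    full wavelength; the -3 dB rule above always meets or exceeds it for a
    non-ideal (Butterworth) filter.
    """
    if f_lo <= 0:
        raise ValueError(f"f_lo must be positive, got {f_lo}")
    wavelength = 1.0 / f_lo
    return wavelength, wavelength / 2.0
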