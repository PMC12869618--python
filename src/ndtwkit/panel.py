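"""The universal input container: subjects x channels x timepoints with TR and band metadata.

On disk a panel is a directory of one CSV per subject (rows = timepoints,
columns = channel labels) plus a YAML manifest listing the subject files,
the repetition time (TR, seconds per sample) and the frequency band.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

RAW_BAND = "raw"


@dataclasses.dataclass
class TimeSeriesPanel:
    """Multichannel time-series panel.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_channels, n_timepoints)
    tr : float
        Sampling interval in seconds (fMRI repetition time).
    band : tuple of (f_lo, f_hi) in Hz, or ``"raw"`` for unfiltered data.
    channel_labels, subject_ids : optional label lists; defaulted if omitted.
    """

    data: np.ndarray
    tr: float
    band: tuple[float, float] | str = RAW_BAND
    channel_labels: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # single subject convenience
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError(
                f"panel data must be (n_subjects, n_channels, n_timepoints); got shape {self.data.shape}"
            )
        if self.n_timepoints < 2:
            raise ValueError("panel needs at least 2 timepoints")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.band != RAW_BAND:
            f_lo, f_hi = self.band
            nyq = 1.0 / (2.0 * self.tr)
            if not (0 < f_lo < f_hi <= nyq):
                raise ValueError(
                    f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < f_lo < f_hi <= Nyquist = {nyq} Hz"
                )
            self.band = (float(f_lo), float(f_hi))
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if self.subject_ids is None:
            self.subject_ids = [f"sub{i + 1}" for i in range(self.n_subjects)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length mismatch")
        if len(self.subject_ids) != self.n_subjects:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def require_finite(self) -> None:
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at subject {self.subject_ids[bad[0]]}, "
                f"channel {self.channel_labels[bad[1]]}, t={bad[2]}"
            )

    def with_data(self, data: np.ndarray, band=None) -> "TimeSeriesPanel":
        """Copy of the panel with replaced data (and optionally band metadata)."""
        return TimeSeriesPanel(
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            band=self.band if band is None else band,
            channel_labels=list(self.channel_labels),
            subject_ids=list(self.subject_ids),
        )


def channel_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Unordered channel pairs (i, j), i < j, in row-major order.

    This fixed order defines the pair axis of every pairwise output
    (53 channels -> 1378 pairs).
    """
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def save_panel(panel: TimeSeriesPanel, out_dir: str | Path) -> Path:
    """Write a panel as per-subject CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for s, sid in enumerate(panel.subject_ids):
        fname = f"{sid}.csv"
        df = pd.DataFrame(panel.data[s].T, columns=panel.channel_labels)
        df.to_csv(out_dir / fname, index=False)
        files.append(fname)
    manifest = {
        "tr": float(panel.tr),
        "band": "raw" if panel.band == RAW_BAND else [panel.band[0], panel.band[1]],
        "subjects": [{"id": sid, "file": f} for sid, f in zip(panel.subject_ids, files)],
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def load_panel(manifest_path: str | Path) -> TimeSeriesPanel:
    """Load a panel from a manifest written by :func:`save_panel` (or by hand)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    subject_ids, arrays = [], []
    labels = None
    for entry in manifest["subjects"]:
        path = base / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"subject file missing for {entry['id']}: {path}")
        df = pd.read_csv(path)
        if labels is None:
            labels = list(df.columns)
        elif list(df.columns) != labels:
            raise ValueError(f"channel labels differ in {path}")
        subject_ids.append(str(entry["id"]))
        arrays.append(df.to_numpy(dtype=float).T)
    band = manifest.get("band", "raw")
    if isinstance(band, (list, tuple)):
        band = (float(band[0]), float(band[1]))
    return TimeSeriesPanel(
        data=np.stack(arrays),
        tr=float(manifest["tr"]),
        band=band,
        channel_labels=labels,
        subject_ids=subject_ids,
    )
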