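"""End-to-end orchestration: a validated run configuration and the full pipeline.

The pipeline runs prep (filter + z-score) -> pairwise nDTW and
time-resolved disparity -> edge trim + state clustering -> per-subject and
aggregate Markov analytics, writing CSV/JSON outputs stamped with the
configuration hash so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import markov_metrics as mm
from . import state_dynamics as sd
from .dtw_core import DtwParams, pairwise_ndtw_frame
from .panel import TimeSeriesPanel, channel_pairs, load_panel
from .signal_prep import apply_zero_phase, design_bandpass, dtw_window_from_cutoff, zscore
from .time_resolved import disparity_tensor

logger = logging.getLogger("ndtwkit")


@dataclasses.dataclass
class RunConfig:
    """Stage parameters for a full run; every stochastic stage carries an explicit seed."""

    manifest: str
    out_dir: str
    band: tuple[float, float] = (0.01, 0.198)
    zscore: bool = True
    gamma: float = 1.5
    window: int | str = "auto"  # "auto" -> dtw_window_from_cutoff(band[0], tr)
    trim: int = 5
    k_max: int = 10
    kmeans_reps: int = 20
    kmeans_max_iter: int = 10000
    kmeans_seed: int | None = 11
    mixing_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.kmeans_seed is None:
            raise ValueError("config error: the k-means stage is stochastic and needs a seed")
        if self.window != "auto" and int(self.window) < 1:
            raise ValueError("window must be 'auto' or a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "band" in raw and isinstance(raw["band"], (list, tuple)):
            raw["band"] = tuple(float(v) for v in raw["band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def resolve_window(window: int | str, f_lo: float, tr: float) -> int:
    return dtw_window_from_cutoff(f_lo, tr) if window == "auto" else int(window)


def prep_panel(panel: TimeSeriesPanel, band: tuple[float, float], do_zscore: bool = True):
    """Filter a raw panel into a band and optionally z-score it."""
    spec = design_bandpass(band[0], band[1], panel.tr)
    out = apply_zero_phase(panel, spec)
    if do_zscore:
        out = zscore(out)
    return out, spec


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle and writes it to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s", config.config_hash())
        panel = load_panel(config.manifest)
        logger.info(
            "stage prep: %d subjects x %d channels x %d timepoints, TR %.3f s",
            panel.n_subjects, panel.n_channels, panel.n_timepoints, panel.tr,
        )
        try:
            prepped, spec = prep_panel(panel, config.band, config.zscore)
        except Exception as err:
            raise RuntimeError(f"stage prep failed: {err}") from err

        w = resolve_window(config.window, config.band[0], panel.tr)
        params = DtwParams(gamma=config.gamma, window=w)
        logger.info("stage ndtw: gamma=%.3g window=%d", params.gamma, params.window)
        try:
            pair_frame = pairwise_ndtw_frame(prepped, params)
            tensor = disparity_tensor(prepped, params)
        except Exception as err:
            raise RuntimeError(f"stage ndtw/trdtw failed: {err}") from err
        pair_frame.to_csv(out_dir / "ndtw_pairs.csv", index=False)

        try:
            trimmed = sd.trim_edges(tensor, config.trim)
            model = sd.fit_states(
                trimmed,
                k_range=range(1, config.k_max + 1),
                reps=config.kmeans_reps,
                max_iter=config.kmeans_max_iter,
                seed=config.kmeans_seed,
            )
        except Exception as err:
            raise RuntimeError(f"stage states failed: {err}") from err
        display, roles = sd.orient_states(model)
        labels = sd.split_labels(model, panel.n_subjects, trimmed.shape[-1])
        logger.info("stage states: selected k=%d roles=%s", model.k, roles)

        summaries = {}
        tms = []
        for s, sid in enumerate(panel.subject_ids):
            tm = mm.transition_matrix(labels[s], model.k, subject_id=sid)
            tms.append(tm)
            occ = mm.dwell_occupancy(labels[s], model.k)
            entry = {
                "ergodic": mm.is_ergodic(tm.P),
                "mean_dwell": occ.mean_dwell.tolist(),
                "occupancy_pct": occ.occupancy.tolist(),
            }
            if entry["ergodic"]:
                cs = mm.chain_summary(tm.P, tol=config.mixing_tol)
                entry.update(
                    pi=cs.pi.tolist(),
                    spectral_gap=cs.spectral_gap,
                    mixing_time=cs.mixing_time,
                    entropy_rate_bits=cs.entropy_rate_bits,
                    entropy_rate_pct=cs.entropy_rate_pct,
                )
            summaries[sid] = entry
        agg = mm.aggregate_transition_matrix(tms)
        agg_summary = mm.chain_summary(agg.P, tol=config.mixing_tol) if mm.is_ergodic(agg.P) else None
        logger.info("stage markov: %d/%d ergodic subjects", sum(v["ergodic"] for v in summaries.values()), len(summaries))

        pairs = channel_pairs(panel.n_channels)
        centroid_frame = pd.DataFrame(
            model.centroids,
            columns=[f"{panel.channel_labels[i]}|{panel.channel_labels[j]}" for i, j in pairs],
        )
        centroid_frame.insert(0, "state", np.arange(model.k) + 1)
        centroid_frame.to_csv(out_dir / "state_centroids.csv", index=False)
        label_frame = pd.DataFrame(labels.T + 1, columns=panel.subject_ids)
        label_frame.to_csv(out_dir / "state_labels.csv", index=False)

        bundle = {
            "config_hash": config.config_hash(),
            "filter": spec.to_dict(),
            "window": w,
            "k": model.k,
            "wss_curve": {str(k): v for k, v in model.wss_curve.items()},
            "roles": roles,
            "subjects": summaries,
            "aggregate": None
            if agg_summary is None
            else {
                "P": agg.P.tolist(),
                "pi": agg_summary.pi.tolist(),
                "spectral_gap": agg_summary.spectral_gap,
                "mixing_time": agg_summary.mixing_time,
                "entropy_rate_bits": agg_summary.entropy_rate_bits,
                "entropy_rate_pct": agg_summary.entropy_rate_pct,
            },
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
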