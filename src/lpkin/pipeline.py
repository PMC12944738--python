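"""High-level composition: detections in, per-repetition metrics out."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .errors import InsufficientDataError
from .kinematics import compute_kinematics
from .obb_geometry import build_end_tracks, calibrate, read_obb_detections
from .phase_detection import detect_concentric_phases, rep_metrics

logger = logging.getLogger(__name__)

__all__ = ["analyze_detections", "metrics_frame"]


def analyze_detections(
    source: str | Path,
    config: RunConfig,
    trial_id: str = "trial",
) -> pd.DataFrame:
    """Full pipeline on one detections source; returns a rep-metrics table.

    Contiguous blocks separated by long detector dropouts are analysed
    independently and their repetitions concatenated in time order.
    """
    detections = read_obb_detections(
        source,
        dialect=config.dialect,  # type: ignore[arg-type]
        image_size=(config.image_width, config.image_height),
    )
    tracks = build_end_tracks(
        detections, fps=config.fps, image_height=config.image_height,
        max_gap=config.max_gap,
    )
    fcfg = config.filter_config()
    rows = []
    rep_counter = 0
    for track in tracks:
        try:
            traj = calibrate(track, config.L_real)
            kin = compute_kinematics(traj, config.mass_m, fcfg, g=config.g)
        except InsufficientDataError as exc:
            logger.warning("skipping short block: %s", exc)
            continue
        phases = detect_concentric_phases(
            kin.v, config.fps, config.v_threshold, config.min_frames
        )
        frame_offset = int(track.frame_indices[0])
        for rm in rep_metrics(kin, phases, fcfg):
            rows.append({
                "trial_id": trial_id,
                "rep_index": rep_counter,
                "ts": rm.phase.ts + frame_offset,
                "te": rm.phase.te + frame_offset,
                "duration_s": rm.phase.duration_s,
                "peak_velocity_mps": rm.peak_velocity,
                "mean_velocity_mps": rm.mean_velocity,
                "peak_power_w": rm.peak_power,
                "mean_power_w": rm.mean_power,
            })
            rep_counter += 1
    return metrics_frame(rows)


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    columns = ["trial_id", "rep_index", "ts", "te", "duration_s",
               "peak_velocity_mps", "mean_velocity_mps",
               "peak_power_w", "mean_power_w"]
    return pd.DataFrame(rows, columns=columns)
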