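"""Concentric-phase segmentation and per-repetition metric extraction.

A concentric phase is the interval where the load moves upward with
meaningful speed.  Candidate frames must satisfy both the direction
criterion (v > 0) and the significance criterion (v above a 0.5 m/s noise
threshold); maximal runs of candidates are merged into intervals and runs
shorter than a minimum duration (5 frames, ~0.1 s at 50 fps) are discarded
as transients.  An optional angle criterion (strictly increasing bar
angle) can additionally be required; it is off by default because the two
velocity criteria alone reproduce the intended segmentation.

Per phase, four indicators are extracted from the velocity and power
series: the peak (Savitzky–Golay smoothing followed by a width-5 sliding
maximum, then the maximum) and the time-weighted mean (trapezoidal
integral over the phase divided by its duration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .kinematics import KinematicSeries
from .signal_filters import FilterConfig, sg_smooth, sliding_max

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentricPhase",
    "RepMetrics",
    "detect_concentric_phases",
    "phase_peak",
    "phase_mean",
    "rep_metrics",
]


@dataclass(frozen=True)
class ConcentricPhase:
    """Inclusive frame bounds [ts, te] of one concentric phase."""

    ts: int
    te: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.te < self.ts:
            raise ValidationError(f"te ({self.te}) < ts ({self.ts})")

    @property
    def n_frames(self) -> int:
        return self.te - self.ts + 1


@dataclass(frozen=True)
class RepMetrics:
    """The four per-repetition indicators for one concentric phase."""

    rep_index: int
    peak_velocity: float   # m/s
    mean_velocity: float   # m/s
    peak_power: float      # W
    mean_power: float      # W
    phase: ConcentricPhase


def detect_concentric_phases(
    v: np.ndarray,
    fps: float,
    v_threshold: float = 0.5,
    min_frames: int = 5,
    theta: np.ndarray | None = None,
) -> list[ConcentricPhase]:
    """Find concentric phases in a velocity series.

    Parameters
    ----------
    v : array
        Tangential velocity in m/s, frame-uniform.
    fps : float
        Frame rate in Hz; phase duration is ``(te - ts) / fps``.
    v_threshold : float
        Significance threshold in m/s (default 0.5).
    min_frames : int
        Minimum merged-interval length in frames (default 5).
    theta : array, optional
        When given, candidate frames must additionally have strictly
        increasing angle (the optional angle criterion).
    """
    v = np.asarray(v, dtype=float)
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    candidates = (v > 0.0) & (v > v_threshold)
    if theta is not None:
        theta = np.asarray(theta, dtype=float)
        rising = np.zeros_like(candidates)
        rising[1:] = np.diff(theta) > 0.0
        candidates &= rising

    phases: list[ConcentricPhase] = []
    padded = np.concatenate([[False], candidates, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        ts, te = int(start), int(stop - 1)
        if te - ts + 1 < min_frames:
            continue
        phases.append(ConcentricPhase(ts=ts, te=te, duration_s=(te - ts) / fps))
    return phases


def phase_peak(
    x: np.ndarray,
    phase: ConcentricPhase,
    cfg: FilterConfig,
    k: int = 5,
) -> float:
    """Peak value within a phase: max of sliding-max of the SG-smoothed segment.

    The SG window shrinks automatically inside short phases (logged by the
    smoothing operator).  Because the final step takes a global maximum,
    the result equals the maximum of the smoothed segment itself; the
    sliding-max stage is retained for fidelity to the extraction recipe.
    """
    x = np.asarray(x, dtype=float)
    if phase.ts < 0 or phase.te >= x.size:
        raise IndexError(
            f"phase [{phase.ts}, {phase.te}] outside series of length {x.size}"
        )
    segment = x[phase.ts:phase.te + 1]
    smoothed = sg_smooth(segment, cfg)
    k_eff = min(k, segment.size if segment.size % 2 == 1 else segment.size - 1)
    return float(np.max(sliding_max(smoothed, k_eff)))


def phase_mean(x: np.ndarray, phase: ConcentricPhase, dt: float) -> float:
    """Time-weighted mean over a phase: trapezoidal integral / duration."""
    if phase.te == phase.ts:
        raise ValidationError("degenerate phase of zero duration")
    x = np.asarray(x, dtype=float)
    segment = x[phase.ts:phase.te + 1]
    Tc = (phase.te - phase.ts) * dt
    return float(np.trapezoid(segment, dx=dt) / Tc)


def rep_metrics(
    kin: KinematicSeries,
    phases: list[ConcentricPhase],
    cfg: FilterConfig,
    k: int = 5,
) -> list[RepMetrics]:
    """Extract the four indicators for every detected phase, in time order."""
    out: list[RepMetrics] = []
    for i, phase in enumerate(phases):
        out.append(RepMetrics(
            rep_index=i,
            peak_velocity=phase_peak(kin.v, phase, cfg, k),
            mean_velocity=phase_mean(kin.v, phase, kin.dt),
            peak_power=phase_peak(kin.P, phase, cfg, k),
            mean_power=phase_mean(kin.P, phase, kin.dt),
            phase=phase,
        ))
    return out
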