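"""Planar rigid-body rotation kinematics, force and power for the landmine press.

The bar is modelled as a rigid body rotating in the sagittal plane about a
stationary pivot (the anchored end).  From the calibrated moving-end
trajectory the chain computes

* the bar angle above the horizontal, ``theta(t) = atan2(y, x)`` in the
  y-up pivot-origin frame, phase-unwrapped so successive differences stay
  within +/- pi;
* angular velocity ``omega = d theta / dt`` (central difference of the
  Savitzky–Golay-smoothed angle);
* angular acceleration ``alpha = d omega / dt`` (central difference,
  zero-phase low-passed);
* tangential linear velocity ``v = L * omega`` of the moving end at radius
  L (the full bar length), zero-phase low-passed;
* tangential force ``F = m L alpha + m g sin(theta)`` combining the
  inertial term for the end-concentrated load mass and the model's
  gravitational term;
* mechanical power ``P = F * v``.

Force and power are model-based estimates (point mass at the moving end,
no friction, no out-of-plane motion), not direct measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .obb_geometry import CalibratedTrajectory
from .signal_filters import FilterConfig, butter_zerophase, central_diff, sg_smooth

__all__ = [
    "KinematicSeries",
    "angle_series",
    "unwrap_angles",
    "angular_velocity",
    "angular_acceleration",
    "linear_velocity",
    "tangential_force",
    "mechanical_power",
    "compute_kinematics",
    "STANDARD_GRAVITY",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass
class KinematicSeries:
    """Time-aligned kinematic arrays for one contiguous trajectory block.

    ``v`` is the low-passed tangential velocity actually used downstream;
    the raw identity ``v_raw = L * omega`` holds elementwise before that
    low-pass.  ``unwrap_offsets`` holds the integer number of 2*pi turns
    added to each raw angle sample by phase unwrapping.
    """

    t: np.ndarray
    theta_raw: np.ndarray        # rad, in (-pi, pi]
    theta_unwrapped: np.ndarray  # rad
    theta_smooth: np.ndarray     # rad, SG-smoothed unwrapped angle
    omega: np.ndarray            # rad/s
    alpha: np.ndarray            # rad/s^2
    v: np.ndarray                # m/s (low-passed)
    F: np.ndarray                # N (model estimate)
    P: np.ndarray                # W (model estimate)
    unwrap_offsets: np.ndarray   # integer k(t)
    dt: float
    mass_m: float
    g: float
    L: float
    estimated: bool = True       # F and P are model outputs, not measurements

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export for plotting or audit."""
        return pd.DataFrame({
            "t": self.t,
            "theta": self.theta_unwrapped,
            "omega": self.omega,
            "alpha": self.alpha,
            "v": self.v,
            "F": self.F,
            "P": self.P,
        })


def angle_series(traj: CalibratedTrajectory) -> np.ndarray:
    """Bar angle above the horizontal via the four-quadrant arctangent."""
    rel = traj.moving_m - traj.pivot_m
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii == 0.0):
        bad = int(np.argmax(radii == 0.0))
        raise DegenerateGeometryError(
            f"moving end coincides with the pivot at sample {bad}"
        )
    return np.arctan2(rel[:, 1], rel[:, 0])


def unwrap_angles(theta: np.ndarray) -> np.ndarray:
    """Add integer multiples of 2*pi so successive differences are <= pi.

    The first sample is returned unchanged; a shift of the whole series by
    2*pi*c propagates exactly.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValidationError("cannot unwrap an empty series")
    return np.unwrap(theta)


def angular_velocity(theta: np.ndarray, cfg: FilterConfig, dt: float) -> np.ndarray:
    """omega = central difference of the SG-smoothed (unwrapped) angle."""
    return central_diff(sg_smooth(theta, cfg), dt)


def angular_acceleration(omega: np.ndarray, cfg: FilterConfig, dt: float) -> np.ndarray:
    """alpha = central difference of omega, then zero-phase low-passed."""
    return butter_zerophase(central_diff(omega, dt), cfg)


def linear_velocity(
    omega: np.ndarray, L: float, cfg: FilterConfig | None = None
) -> np.ndarray:
    """Tangential velocity v = L * omega; low-passed when a config is given."""
    if L <= 0:
        raise ValidationError(f"L must be positive, got {L}")
    v = L * np.asarray(omega, dtype=float)
    if cfg is not None:
        v = butter_zerophase(v, cfg)
    return v


def tangential_force(
    alpha: np.ndarray,
    theta: np.ndarray,
    m: float,
    L: float,
    g: float = STANDARD_GRAVITY,
) -> np.ndarray:
    """F = m L alpha + m g sin(theta): inertial plus gravitational terms."""
    if m <= 0 or L <= 0:
        raise ValidationError("mass and length must be positive")
    return m * L * np.asarray(alpha, dtype=float) + m * g * np.sin(theta)


def mechanical_power(F: np.ndarray, v: np.ndarray) -> np.ndarray:
    """P = F * v elementwise."""
    return np.asarray(F, dtype=float) * np.asarray(v, dtype=float)


def compute_kinematics(
    traj: CalibratedTrajectory,
    mass_m: float,
    cfg: FilterConfig | None = None,
    g: float = STANDARD_GRAVITY,
    alpha_from_filtered_velocity: bool = False,
) -> KinematicSeries:
    """Run the full chain from calibrated coordinates to power.

    Raw 2-D coordinates are SG-smoothed first, then the angle, angular
    velocity, acceleration, tangential velocity, force and power are
    derived.  ``alpha_from_filtered_velocity`` switches the acceleration
    input from the smoothed-but-not-low-passed omega (default) to the
    low-passed velocity divided by L; both orders are defensible given the
    processing chain's ambiguity, and the choice is recorded on the result.
    """
    if cfg is None:
        cfg = FilterConfig(fs=traj.fps)
    dt = 1.0 / traj.fps

    smoothed = CalibratedTrajectory(
        t=traj.t,
        moving_m=np.column_stack([
            sg_smooth(traj.moving_m[:, 0], cfg),
            sg_smooth(traj.moving_m[:, 1], cfg),
        ]),
        pivot_m=traj.pivot_m,
        scale_s=traj.scale_s,
        L_pixel_mean=traj.L_pixel_mean,
        L_real=traj.L_real,
        fps=traj.fps,
    )
    theta_raw = angle_series(smoothed)
    theta_unwrapped = unwrap_angles(theta_raw)
    offsets = np.round((theta_unwrapped - theta_raw) / (2.0 * np.pi)).astype(int)

    theta_smooth = sg_smooth(theta_unwrapped, cfg)
    omega = central_diff(theta_smooth, dt)
    v = linear_velocity(omega, traj.L_real, cfg)
    if alpha_from_filtered_velocity:
        alpha = butter_zerophase(central_diff(v / traj.L_real, dt), cfg)
    else:
        alpha = angular_acceleration(omega, cfg, dt)
    F = tangential_force(alpha, theta_smooth, mass_m, traj.L_real, g)
    P = mechanical_power(F, v)

    return KinematicSeries(
        t=traj.t,
        theta_raw=theta_raw,
        theta_unwrapped=theta_unwrapped,
        theta_smooth=theta_smooth,
        omega=omega,
        alpha=alpha,
        v=v,
        F=F,
        P=P,
        unwrap_offsets=offsets,
        dt=dt,
        mass_m=mass_m,
        g=g,
        L=traj.L_real,
    )
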