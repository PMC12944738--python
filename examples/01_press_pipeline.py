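"""Simulate a landmine press and recover per-rep velocity and power.

Generates a clean three-repetition trial (50 fps, 2.20 m bar, 25 kg load,
40 deg -> 80 deg presses of 0.8 s), runs the detection-to-metrics pipeline
on the rendered oriented-bounding-box labels, and compares the recovered
peak velocity with the closed-form ground truth.
"""

import numpy as np

from lpkin import (
    FilterConfig,
    SyntheticPressConfig,
    build_end_tracks,
    calibrate,
    compute_kinematics,
    detect_concentric_phases,
    rep_metrics,
    simulate_press,
)
from lpkin.synthetic import peak_angular_velocity

cfg = SyntheticPressConfig(seed=0, n_reps=3)
out = simulate_press(cfg)
print(f"simulated {len(out.detections)} frames, {cfg.n_reps} repetitions")

(track,) = build_end_tracks(out.detections, cfg.fps, cfg.image_size[1])
traj = calibrate(track, cfg.L_real)
print(f"calibration: {traj.scale_s * 1000:.3f} mm/px "
      f"(true {1000 / cfg.pixel_scale:.3f} mm/px)")

kin = compute_kinematics(traj, cfg.mass_m)
phases = detect_concentric_phases(kin.v, cfg.fps)
metrics = rep_metrics(kin, phases, FilterConfig(fs=cfg.fps))

v_true = cfg.L_real * peak_angular_velocity(cfg)
print(f"analytic peak velocity: {v_true:.3f} m/s\n")
print("rep  peak_v[m/s]  mean_v[m/s]  peak_P[W]  mean_P[W]  duration[s]")
for m in metrics:
    print(f"{m.rep_index:>3}  {m.peak_velocity:>11.3f}  {m.mean_velocity:>11.3f}"
          f"  {m.peak_power:>9.1f}  {m.mean_power:>9.1f}"
          f"  {m.phase.duration_s:>11.2f}")

err = abs(metrics[0].peak_velocity - v_true) / v_true * 100
print(f"\npeak-velocity recovery error: {err:.2f}% "
      "(smoothing slightly attenuates the true peak)")
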