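# lpkin — landmine-press kinematics from oriented-bounding-box detections

`lpkin` turns per-frame **oriented bounding box (OBB)** detections of a
barbell's two ends into per-repetition **concentric-phase velocity and power
metrics**, and provides the paired **method-agreement statistics** used to
compare such a markerless vision measurement against a second device (e.g. a
cable linear-position transducer).

In a landmine press one bar end is anchored to the floor while the athlete
presses the free end along an arc.  Filming the movement side-on and detecting
both bar ends per frame, the bar can be modelled as a rigid body in planar
rotation about the anchored pivot:

- bar angle above the horizontal: `θ(t) = atan2(y_m − y_f, x_m − x_f)`,
  phase-unwrapped so |Δθ| ≤ π;
- angular velocity `ω = dθ/dt` (central difference of the Savitzky–Golay
  smoothed angle, window 9 / order 3);
- tangential velocity of the moving end: `v = L·ω` with `L = 2.20 m` (full bar
  length), zero-phase Butterworth low-passed at 6 Hz;
- angular acceleration `α = dω/dt` (central difference, low-passed);
- tangential force `F = mLα + mg·sin θ` and power `P = F·v` — model-based
  estimates for the end-concentrated load mass `m`.

Concentric phases are maximal runs of frames with `v > 0` **and**
`v > 0.5 m/s`, at least 5 frames long (~0.1 s at 50 fps).  Per phase the
toolkit extracts peak velocity (SG smoothing + width-5 sliding maximum, then
max), mean velocity (trapezoidal time-weighted average), and the analogous
power indicators.

The agreement module implements the standard two-method comparison battery:
Pearson r with interpretation bands, Bland–Altman bias and 95% limits of
agreement (`bias ± 1.96·SD`) with confidence intervals, a paired t-test, the
paired Cohen's d (`mean(diff)/SD(diff)`), and Deming errors-in-variables
regression (λ = 1) with jackknife CIs and fixed/proportional-bias flags.

A synthetic-trial generator renders rigid planar rotations as OBB label files
with closed-form ground truth (minimum-jerk angle profiles, corner noise,
frame dropout), and produces paired-method tables with the known
radius-induced proportional bias (2.20 m vs 2.05 m effective radius, slope
2.20/2.05 ≈ 1.073), so every stage is testable without recordings.

## Worked example

`python examples/01_press_pipeline.py` simulates a clean three-rep trial
(50 fps, 2.20 m bar, 25 kg, 40°→80° presses of 0.8 s) and runs the full
pipeline on the rendered labels:

```
simulated 591 frames, 3 repetitions
calibration: 2.500 mm/px (true 2.500 mm/px)
analytic peak velocity: 3.600 m/s

rep  peak_v[m/s]  mean_v[m/s]  peak_P[W]  mean_P[W]  duration[s]
  0        3.592        2.472     1277.8      515.1         0.60
  1        3.592        2.472     1277.8      515.1         0.60
  2        3.592        2.472     1277.8      515.1         0.60

peak-velocity recovery error: 0.23% (smoothing slightly attenuates the true peak)
```

The recovered peak velocity (3.592 m/s) sits 0.23% below the closed-form
truth `L·ω_max = 2.20 × 1.636 = 3.600 m/s`; the 0.60 s detected duration is
the part of the 0.8 s ascent above the 0.5 m/s threshold.  See
`examples/02_method_agreement.py` (agreement battery on radius-biased pairs)
and `examples/03_cross_table_effect_sizes.py` (effect sizes recovered from
published Bland–Altman summaries).

## Command line

A thin CLI wraps the same library functions:

```bash
lpkin simulate --seed 7 --reps 3 --noise-px 2 --out fixtures/
lpkin analyze --detections fixtures/labels --fps 50 --bar-length 2.20 \
      --mass 25 --out metrics.csv
lpkin compare --paired pairs.csv --group-by load,indicator --out report.json
```

`analyze` writes a rep-metrics CSV plus a JSON mirror embedding the effective
configuration and any processing warnings; `compare` writes one agreement
report per indicator × load group.

## Layout

- `src/lpkin/obb_geometry.py` — OBB parsing, principal-axis midpoints, end
  classification, gap-tolerant tracking, pixel-to-metre calibration
- `src/lpkin/signal_filters.py` — SG smoothing, zero-phase Butterworth,
  central difference, sliding maximum
- `src/lpkin/kinematics.py` — angle/ω/α/v/F/P chain
- `src/lpkin/phase_detection.py` — concentric segmentation and rep metrics
- `src/lpkin/agreement.py` — the method-comparison battery
- `src/lpkin/synthetic.py` — ground-truth press and paired-method generators
- `src/lpkin/datasets.py` — bundled published agreement summaries
- `docs/methods.md` — model assumptions, parameter choices, limitations
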