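# Methods

## Model and assumptions

The barbell is treated as a rigid body rotating in a single (sagittal) plane
about a stationary pivot — the anchored end of the landmine attachment.  The
camera views the plane frontally, so perspective reduces to a single scalar
pixel-to-metre scale; lens distortion, out-of-plane motion, anchor compliance
and grip micro-motion are neglected.  For force and power the load mass is
concentrated at the moving end, so

- `v = L·ω` (tangential velocity at radius `L`, the full bar length),
- `F = m·L·α + m·g·sin θ` (inertial plus gravitational terms, with `θ`
  measured from the horizontal),
- `P = F·v`.

Force and power are therefore **model estimates**, not measurements, and the
`KinematicSeries` carries an `estimated` flag to that effect.

A note on the gravity term: for an angle measured from the horizontal the
geometric tangential component of gravity would be `m·g·cos θ`; the model's
`sin θ` convention corresponds to the potential `U = −m·g·L·cos θ`.  The
package implements the model as stated, and its energy-balance test checks
`∫P dt ≈ ΔU + ΔKE` using that model-consistent potential — the test documents
the model's internal consistency, not agreement with the geometric height
gain `L·Δ(sin θ)`.

## Geometry and calibration

Each frame's OBB is reduced to two bar-end points.  For a whole-bar box the
principal axis is the longer side (`L1 = |P1−P2|` vs `L2 = |P2−P3|`, ties
taking the second branch) and the ends are the midpoints of the two opposing
longer sides.  For per-end marker boxes the box centers are used directly.
Classification uses image height: the moving end is the one with smaller
image-y (image coordinates grow downward); an exact tie labels the second
endpoint moving.  When marker class labels disagree with the height rule the
rule wins and a warning is logged, since the height constraint is physical
while labels can swap.

Calibration averages the per-frame pixel distance between the ends to get the
bar's pixel length and sets `s = L_real / L_pixel` (default
`L_real = 2.20 m`).  The pivot used as the coordinate origin is the per-axis
**median** of the fixed-end detections — robust to detector jitter — while
the calibration average uses per-frame distances as defined.  All kinematics
run in a y-up, origin-at-pivot metre frame so pressing upward gives
increasing `θ` and positive `v`.

Detector dropouts up to `max_gap = 5` frames (0.1 s at 50 fps, matching the
minimum-interval granularity used in segmentation) are filled by linear
interpolation and flagged; longer gaps split the recording into contiguous
blocks analysed independently.  `build_end_tracks` therefore returns a list
of tracks rather than a single one.

## Filtering chain

All tunables live in `FilterConfig` with these defaults:

| parameter | default | unit | role |
|---|---|---|---|
| `sg_window` | 9 | frames | Savitzky–Golay window (0.18 s at 50 fps) |
| `sg_order` | 3 | — | SG polynomial order |
| `butter_cutoff` | 6 | Hz | zero-phase low-pass cutoff |
| `butter_order` | 4 | — | Butterworth order per pass |

The chain: raw 2-D coordinates are SG-smoothed; the unwrapped angle is SG
smoothed and centrally differenced to `ω`; `v = L·ω` is low-passed; `α` is
the central difference of `ω` (the smoothed but not low-passed series), then
low-passed.  Differentiating the low-passed velocity instead is available via
`alpha_from_filtered_velocity=True`; the default order was chosen because the
low-pass is motivated as a velocity-peak-timing correction and re-using its
output for `α` would compound attenuation.  The Butterworth stage is a
second-order-section forward–backward pass with even-extension padding and no
cutoff pre-warping, so the effective −3 dB point of the double pass sits
slightly below 6 Hz.  SG edge handling fits the local polynomial inside the
truncated window (`mode="interp"`), preserving endpoint trends in short
phases.  Central differences use one-sided first differences at the two
endpoints.

Degenerate-input policy: series shorter than the SG window shrink the window
to the largest valid odd length (logged at WARNING) so short repetitions stay
analysable; series shorter than `sg_order + 2` samples, or shorter than
3 × the Butterworth order, raise `InsufficientDataError` instead of returning
silently wrong numbers.

## Segmentation and per-rep indicators

Candidate frames must satisfy `v > 0` **and** `v > 0.5 m/s` (both checked
literally even though the second implies the first); maximal candidate runs
form intervals and intervals shorter than 5 frames are discarded.  Both
thresholds are strict inequalities, and the minimum length applies to the
merged interval.  An optional angle criterion (strictly increasing `θ`) can
be enabled but is off by default: its intended predicate is not precisely
defined in the source methodology, and the two velocity criteria alone
reproduce the described behaviour.

Peak extraction smooths the phase segment (SG, window auto-shrunk), applies a
width-5 sliding maximum with edge truncation, and takes the maximum; because
the last step is a global max, the result equals the max of the smoothed
segment, and the sliding-max stage is kept for fidelity to the extraction
recipe.  The mean is the trapezoidal integral over the phase divided by
`T_c = (t_e − t_s)·Δt`; trapezoidal quadrature is the natural discretisation
of the time-weighted average for frame-sampled data.

## Agreement battery

Differences are method A − method B throughout.

- **Bland–Altman**: bias = mean difference, LoA = bias ± 1.96·SD (sample SD,
  n−1).  Bias CI by t distribution; each LoA CI uses the approximate
  standard error `SD·√(1/n + 1.96²/(2(n−1)))` with the same t quantile (the
  exact-vs-approximate choice is undocumented in the source protocol; the
  approximate form is the common default).
- **Paired t**: two-sided on n−1 df.  All-zero differences return t = 0,
  p = 1 rather than 0/0.
- **Cohen's d**: the paired convention `mean(diff)/SD(diff)` (d_z).  This
  convention was adopted because it reproduces the published effect-size
  table from the published bias/LoA table (see the cross-table test) — the
  strongest available evidence of the original convention.  Zero-variance
  differences are signalled as degenerate.  Band edges: < 0.2 negligible,
  0.2–0.5 small, 0.5–0.8 medium, ≥ 0.8 large; the source bands leave
  0.8–0.9 unassigned, and this package closes the gap at 0.8.
- **Deming regression** (λ = 1 by default): closed-form errors-in-variables
  slope from the sample (co)variances; CIs by leave-one-out jackknife with a
  t quantile on n−2 df (deterministic given the data).  Fixed bias is
  flagged when the intercept CI excludes 0, proportional bias when the slope
  CI excludes 1.
- **Pearson bands** are applied to |r| with the sign reported separately.

Multiple trials per athlete are pooled as independent pairs; no hierarchical
adjustment is made.  This matches the comparison protocol being emulated but
understates CI widths when trials cluster within athletes — a known caveat.

### Cross-table consistency check

The bundled summaries print bias, LoA and d to two decimals from unrounded
data.  Recomputing d from the printed bias/LoA therefore carries an interval
of uncertainty: the check uses exact interval arithmetic over the ±0.005
input rounding and allows the printed d one unit in its last place (the
standard allowance when cross-checking two independently rounded tables).
All 20 cells are consistent under this rule; one cell (20 kg mean power)
sits a few 10⁻⁵ outside the half-unit interval, which is exactly the
signature of double rounding.

## Synthetic generators

`simulate_press` emulates the capture conditions of a bench study: 50 fps,
1080p frame, pivot near the lower-left corner, 2.20 m bar at 400 px/m,
40°→80° ascents of 0.8 s separated by 1 s dwells, three repetitions, 25 kg
load.  Each ascent follows a minimum-jerk quintic
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`, chosen so `ω` and `α` are closed-form and vanish
at the endpoints (peak `ω = Δθ·(15/8)/T`).  Corner noise is i.i.d. Gaussian
per coordinate; dropout removes whole frames, matching how detector misses
occur.  The generator does **not** model motion blur, occlusion by the
athlete, perspective error from imperfect camera placement, or detector bias
correlated with pose — so passing recovery tests demonstrates correctness of
the geometry/filtering chain, not robustness of any particular detector.

`simulate_paired_methods` draws per-trial peak angular velocities from a
log-normal (median 0.95 rad/s, log-SD 0.23, matching typical press velocity
spreads) and converts them with the two effective radii 2.20 m and 2.05 m
plus independent Gaussian measurement noise (default SD 0.05 m/s per method,
a typical device-level precision).  The known truth — slope 2.20/2.05 ≈
1.0732, intercept 0 — is what the agreement battery must recover.

## Problem sizes used in the shipped checks

The acceptance script and tests use: a 3 × 3 grid of press profiles
(durations 0.6/0.8/1.0 s × amplitudes 30°/40°/50°), 20 noise replicates at
2 px corner noise, and 100 replicates of 500 paired trials for the
proportional-bias detection rate.  These sizes give stable statistics while
keeping the whole suite interactive.

## Known limitations

- Single-plane, single-scale camera model; no lens-distortion correction.
- Force/power inherit every kinematic assumption; they are not validated
  against force-plate data here.
- The eccentric phase is not analysed; no 1RM estimation from load–velocity
  profiles.
- Agreement CIs assume independent pairs (see above).
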