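# Methods

This note documents the models, numerical choices and known limitations of
`rollagait`. It covers the simulator (what the synthetic data does and does
not emulate), the detectors, and the parameter definitions.

## Gait model

A walking trial is a sequence of alternating heel strikes. The step ending
with a side-`s` strike lasts that side's step time `60/cadence ×
step_time_asymmetry[s]` (s). Each step opens with a double-support interval
occupying `1 − single_support_fraction` of the step; the contralateral foot
then swings until its own strike. With the default
`single_support_fraction = 0.62` the cycle is 62% single support, matching
the textbook figure that single support exceeds 60% of the cycle in normal
gait.

The body (and the rollator with it) advances one step length per step, so
the nominal speed is `v = step_length × cadence / 60` (0.554 m/s at the
defaults). The stance foot is fixed in world coordinates; the swing foot
travels between its consecutive footprints — one stride length, twice the
step length in symmetric gait — with a raised-cosine longitudinal velocity
profile (zero velocity *and* acceleration at lift-off and touch-down, peak
speed `2 × stride / swing duration`). Configurations whose implied peak
swing speed exceeds 10 m/s are rejected as infeasible. Feet are placed at
x = −0.30 m (at contact) and y = ±0.12 m in the body frame, which keeps
them inside the default detection area (x ∈ [−1.0, −0.1], y ∈ [−0.45,
0.45] m) throughout the cycle. On turning path segments the pose follows a
constant-curvature arc and footprints follow the body frame.

## Sensor emulation

* **Encoders** (600 Hz): wheel speeds `v ∓ ωL/2` (wheelbase L = 0.55 m)
  integrated to cumulative rim displacement and rounded to the 0.1 mm tick.
* **Handle loads** (2.5 Hz): the total load is `handle_support_mean`
  (optionally scaled per single-support side by `stance_load_factor`, which
  emulates a user unloading an affected leg onto the frame); the
  left-minus-right difference is a smooth cosine-segment oscillation
  peaking `handle_modulation` kg toward the side whose heel just struck, a
  quarter step after contact (the phase relation of load transfer to heel
  strike is not standardized; the quarter-step peak is this package's
  modeling choice). Values are clipped at zero and quantized to 5.5 g.
* **Laser** (5.5 Hz, 1° beams, 6 m range): each beam returns the nearest
  ray/disc intersection with the two 0.06 m-radius leg discs plus Gaussian
  range noise (σ = 0.01 m); with probability `dropout_prob` a scan omits
  one leg entirely (a crude stand-in for occlusion by clothing or the
  frame). What the simulator does **not** emulate: non-circular leg
  cross-sections, trousers/skirts, other people or obstacles in the
  detection area, scan-time skew within a rotation, wheel slip, uneven
  floors, or load-cell drift. Passing tests therefore demonstrate
  correctness of the algorithms under the modeled physics, not robustness
  to every clinical condition.

One seeded generator (`numpy.random.default_rng(seed)`) drives all noise;
draws occur in a fixed order (per scan: dropout coin, occluded-side choice,
per-beam range noise), so identical configurations are bit-reproducible.

## Leg tracking and event detection

Scans are clipped to the closed detection-area rectangle in the base frame.
Each cloud is split by 2-means; Lloyd's iteration runs from **two**
seedings — the previous scan's centroids and a median split on the lateral
coordinate — keeping the lower-cost partition. The tracking prior alone is
unreliable here: at 5.5 Hz a swinging leg moves ~0.4 m between scans,
comparable to the leg separation, and a stale seed then captures the wrong
blob once per cycle. The larger-y centroid is labeled left; centroids
closer than `min_leg_separation` (0.10 m) are treated as a single occluded
leg, assigned to the nearer side; clusters under `min_cluster_points` (3)
are invalid.

Leg velocities are centered finite differences of the centroid
x-coordinate on the laser timeline; gaps up to 2 invalid scans are bridged
linearly, longer gaps leave the velocity undefined. vdiff is formed where
both sides are defined; each contiguous stretch of at least 2 s is linearly
resampled to an internal 50 Hz timeline before filtering. The resampling
matters: the 0.3–3 Hz Butterworth passband would not fit under the 2.75 Hz
Nyquist frequency of the raw scan rate, and peak times gain sub-scan
resolution. Filtering is order-2 Butterworth, applied forward-backward
(zero phase) so event times are not lagged.

Peaks above ±0.1 m/s (`peak_threshold`) give events; peaks closer than
`60/max_cadence` s (0.33 s at the default 180 steps/min ceiling) to a
larger same-sign peak are suppressed. Under the raised-cosine swing the
vdiff peak falls at **mid-swing**, half a swing before the contact, so the
detector shifts each peak forward by `swing_fraction/2 ×` the local
inter-event interval (`swing_fraction = 0.62`, the nominal single-support
share; set 0 to report raw peak times). After this shift, detected events
land within ~0.02 s of the true contacts on default simulations.

## Support phases

Two labelers are provided. The instantaneous rule — double support when
both relative velocities are negative and within 0.15 m/s of each other,
otherwise single support on the slower leg — is exact in the continuous
limit but blurs at the hardware scan rate: a 0.24 s double-support window
spans ~1.3 scans, and experiments with noise-free centroid tracks cap its
per-sample accuracy near 75–90%. When an event sequence is available the
labeler therefore anchors the boundaries on it: each contact opens a
double-support interval of `1 − swing_fraction` of the step, followed by
single support on the contact side. Contacts are localized an order of
magnitude better than per-sample velocities, and the anchored labels agree
with simulation ground truth at ~98% per sample. Intervals shorter than
0.1 s are absorbed by their longer neighbor.

## Force-difference detector (legacy)

fdiff = (left − right) handle load in newtons, resampled to a uniform
internal timeline and low-passed at 3 Hz (zero phase); maxima are left
events, minima right events. fdiff oscillates once per stride (~0.8 Hz),
safely under the 1.25 Hz Nyquist frequency of the 2.5 Hz load stream, so
the slow sampling does not alias it. The detector flags itself invalid
when the peak-to-peak filtered fdiff is below 7 N — the published
reliability floor of the method — but still returns its events for
inspection. Peak prominence must exceed max(0.1 N, 20% of peak-to-peak),
so a flat difference yields no events.

## Parameters and reporting

Events are cleaned to a strictly alternating sequence (same-side
duplicates keep the larger peak); fewer than four events is an error
("insufficient steps"). CAD and WV are computed from their definitions
(`60·NoS/Tr`, `d/Tr`), so the definitional identities hold exactly.
Lengths interpolate the cumulative odometric path distance (trapezoid of
|v| on the encoder timeline) at event times. Dispersions are sample
standard deviations (ddof = 1). Tr is the full session duration; a
motion-gated alternative was considered and rejected for the default
because the simulated trials contain no standing intervals.

UrS is the mean per-step total handle load in kg-force (the raw per-step
force sum in newtons is kept as an auxiliary field; a bare sum grows with
session length and is not comparable across trials). WB is reported
literally as 1/UrS in N⁻¹ and is undefined (None, not infinity) at zero
load. Partial weight bearing uses load samples inside single-support
phases only; steering-speed bins default to edges ±0.1 and ±0.3 rad/s on
the reporting axis (negative = left turn, the negative of odometric ω).

In the multi-session summary table, UrS below 1 kg renders as "<1" and
contributes zero to the column average (the below-detection convention of
the reference table layout); cells are formatted to two decimals with
round-half-even.

## Numerical choices and degenerate inputs

* Odometry smooths wheel speeds over a 50 ms window; at 600 Hz and 0.1 mm
  ticks, raw one-sample differences would jitter by ±0.06 m/s.
* Pose integration uses the exact constant-(v, ω) arc; |ω| < 1e-9 rad/s
  falls back to the straight-line update. θ is wrapped to (−π, π].
* The session format stores all numbers as shortest round-tripping
  decimals (`repr`), making read(write(s)) bit-exact; invalid laser
  returns are the JSON string "inf".
* Empty point clouds, single-blob scans, zero loads and zero-length
  phases are all legal inputs and produce invalid flags / None rather
  than exceptions; genuinely unusable inputs (empty streams,
  non-monotonic time) raise `ValidationError` with the offending index.

## Problem sizes

Default trials are 60 s (~95 steps, 331 scans, 36 001 encoder samples);
the recovery experiments in the test suite span 20 seeded trials with
cadences between 60 and 130 steps/min. A full simulate-plus-analyze cycle
takes well under a second, so the whole suite runs in seconds.
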