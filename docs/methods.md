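# Methods

`gazeflight` analyzes the gaze and flight kinematics of small birds
performing a U-turn flight in a confined arena: take off from a perch,
fly out, turn "on a dime", fly back and land on the same (swinging)
perch.  The pipeline goes from marker-level 3-D kinematic traces to
head-saccade statistics, wingbeat-mode classification, azimuthal
feature-stabilization distributions, and an analysis of which optical
variable most parsimoniously triggers landing.  Because no kinematic
data accompany the original recordings, a synthetic-trial generator
with exact ground truth provides the test surface for every stage.

## Coordinate conventions and data model

All positions are in meters, times in seconds, angles in degrees.  The
planform (top-view) frame has x along the 1 m arena axis and y across
the 0.6 m width; the perch spans the width direction near x = 0, and
the white high-contrast side wall is at y = 0.6.  Yaw 0° points along
+x (away from the perch), yaw 180° faces the perch, and positive yaw is
a leftward (counter-clockwise from above) rotation.  All yaw and
azimuth computations use the horizontal marker components; the vertical
channel is kept only for the altitude-change inclusion criterion.

A trial carries two full-rate head markers (anterior/posterior), sparse
shoulder and wingtip positions sampled at the four annotated stroke
instants per wingbeat (down start, down mid, down end, up mid), the
landing-initiation (tail-pitch) time, and optionally the planform track
of the swinging perch center.  Head yaw is the arctangent of the
anterior-minus-posterior marker vector; body yaw is the forward normal
of the shoulder-to-shoulder vector.  Angles are unwrapped before
smoothing — a U-turn sweeps through more than 180° and smoothing
wrapped angles corrupts the derivatives.

## Whittaker smoothing and cross-validation error

Coordinate and yaw channels are filtered by discrete penalized least
squares (a Whittaker smoother): minimize
`sum w_i (y_i − z_i)² + λ sum (Δ² z_i)²` with 0/1 weights, so missing
samples are interpolated by the roughness penalty.  Second-order
differences are used; this is the standard choice and reproduces the
smoother's well-known similarity to a Savitzky–Golay filter.  Penalty
weights per channel grade: coordinates λ = 100, head yaw λ = 5000, body
yaw λ = 1e6.  The body grade doubles as the interpolator that brings
the wingbeat-rate shoulder channel up to the 2000 Hz camera rate.

The admissibility check is the leave-one-out cross-validation error,
computed exactly from the hat-matrix diagonal as the RMS of
`(y_i − z_i)/(1 − h_ii)` over observed samples (bounds: 0.5 for
coordinates, 1 for head yaw, 2 for body yaw, in signal units).  RMS was
chosen as the norm; at λ = 0 the hat formula degenerates and the exact
penalty-interpolation limit is computed instead.  Derivatives use
central differences with second-order one-sided ends, so a linear ramp
is differentiated exactly and smooth signals obey the usual
`(2πf)³ Δt²/6` interior error bound.

λ is fixed per channel rather than optimized: the grades were chosen
conservatively for this apparatus and automatic λ selection is a
non-goal.

## Saccade detection

Head yaw rate ω is the derivative of the smoothed, unwrapped head yaw.
A saccade is a maximal run of samples with |ω| strictly above 400 °/s
lasting at least 12 ms (24 samples at 2000 Hz); equality at the
threshold does not count, and any sub-threshold gap separates two
events.  The supra-threshold duration is reported as the event's
duration.  For amplitudes, the boundaries are extended outward to the
nearest sample where |ω| falls below a 100 °/s floor or reaches a local
minimum, whichever comes first within 10 ms of the crossing: the
extension recovers the full head turn (onset detection is uncertain by
a few milliseconds) without merging adjacent drift.  Both signed
absolute (arena-frame) and relative (head-minus-body) amplitudes are
computed over the extended boundaries, and both the supra-threshold and
the extended (onset-to-offset) durations are reported; the
amplitude-duration regression uses the extended duration, whose slope
estimates the preferred head angular speed.

Summaries aggregate flight → bird → cohort, in that order — raw events
are never pooled across birds.  The saccadic fraction of a turn is the
summed saccade amplitude magnitude divided by the net head yaw change
over the turn window; it can exceed 100% when saccades overshoot
slightly against the net reorientation.

## Turn segmentation and flight filters

The maneuver is segmented into before/during/after-turn phases from the
planform wingtip positions at mid-downstroke (one point per beat,
averaging left and right tips).  The heading of the segment between
consecutive mid-stroke points is compared with the pre-turn running
heading (circular mean of the first three segments).  The turn starts
at the first segment deviating by more than 20°, walked back across the
incipient deflection (segments deviating by at least one fifth of the
threshold, tolerating a single quiet segment — body rotation can
transiently cancel the lateral chord displacement early in the turn).
The turn ends at the first later segment pair whose headings re-align
within the threshold.  The 20° threshold separates straight-phase
wobble from turn-phase curvature on synthetic traces and is
configurable; the quantitative rule is this package's operationalization
of a segmentation done visually in the original workflow.  A second
deflection bout after re-alignment flags a violated single-U-turn
assumption.

Implementable trial-inclusion criteria: one complete U-turn, head
altitude range below 0.21 m (max − min of the vertical head
coordinate), and a pre-takeoff heading within ±45° of the initial
flight direction.  Camera-coverage, first-attempt-landing and
mesh-occlusion criteria are video-level and cannot be evaluated on
kinematic input.

## Wingbeat modes

Per complete wingbeat the records carry instantaneous frequency
(1/(up-end − down-start)), downstroke/upstroke period ratio, stroke
amplitude (the angle between the most dorsal and most ventral wingtip
position, in radians), wingbeat-averaged flight speed from the head
position derivative, and the advance ratio J = V/(2AfR) with R the
root-to-tip wing length (0.126–0.140 m across birds; default 0.135 m).

Frequency and ratio samples are fitted per bird with a two-component
1-D Gaussian mixture, f(x) = ξ₁N(μ₁,σ₁) + ξ₂N(μ₂,σ₂), by a
hand-written EM: deterministic initialization at the 25th/75th sample
percentiles with equal weights and the pooled SD, a variance floor of
1e-6·var(x) against component collapse, and a per-iteration
log-likelihood monotonicity assertion.  A fit counts as bimodal when
|μ₁ − μ₂| > 2·max(σ₁,σ₂) and min(ξ₁,ξ₂) > 0.1 (the published condition
prints |μ₁ − μ|, read here as μ₂ — the comparison needs two component
means).  Beats are labeled intermittent when their frequency falls
below the bird's fit midpoint (ties to normal); classification uses the
frequency separator only, since a beat gets one label — the ratio
separator is computed and reported but not used for labeling.  The
cross-bird summary takes across-bird means and sample SDs (n−1) of the
component means and midpoints.  Whether the original fits constrained
equal weights is unknown; weights are free here, and the published
parameter sets are stored with balanced weights as plotted.

## Gaze features

The azimuth of an arena feature (wall corners where the white side wall
meets the dark end walls, the two vertical edges of the gray wall
panel, perch center and edges) is the signed planform angle from the
head-yaw heading vector to the head-to-feature vector; positive
azimuths lie in the left visual hemisphere.  When the perch track is
available the perch features follow the swinging perch.  Distributions
use intersaccadic samples only: at full rate, the complement of the
detected saccades' extended boundaries; at wingbeat rate, whole beats
are excluded when the SD of the (four) yaw samples inside them exceeds
10° — the magnitude of feasible horizontal eye movements.

Histograms use left-closed 10° bins on [−90°, 90°]; azimuths outside
the range are dropped from the histogram but kept in the series.  Per
bird, each feature's counts are divided by the summed counts across all
features of that phase (reading "divided by the cumulative sum of all
other feature distributions" as the all-features total; the literal
other-features denominator is available behind a switch and changes
only the scale, not the ordering).  Per-bird distributions are then
averaged across birds.  The ±10° feasible-eye-motion band is an
annotation for display, never a data filter.

## Landing cues

The azimuthal retinal extent of the perch, α, is the absolute
difference of the two perch-edge azimuths per frame (yaw-independent).
α is smoothed with the coordinate-grade settings before
differentiation — the expansion speed Ω = dα/dt amplifies noise
otherwise; differentiating raw α is available via a switch.
RREV = Ω/α and tau = α/Ω; tau is masked where |Ω| is numerically zero
(below 1e-6 °/s), and tau·RREV = 1 wherever both are defined.
Horizontal flight speed is the planform head-position derivative
magnitude; relative speed is the derivative of the head-minus-perch
planform vector.

Trials are aligned at the tail-pitch instant (an input annotation; tail
tracking is video-level, and the synthetic generator emits the instant
α first crosses a configured threshold).  Per time step over
[−85 ms, 0] the coefficient of variation of each parameter across
trials is SD/|mean| (pooled across trials; a per-bird-first option
exists), and the most parsimonious cue is the parameter with the lowest
window-mean c.v.  The final 30 ms visuomotor band is annotated, not
excluded.  The acquisition-rate robustness check decimates α before
differentiation, recomputes the table at the reduced rate (50 Hz by
default) and reports the Spearman rank correlation of the parameter
ordering against the full-rate analysis.

## The synthetic generator

The generator emulates the study conditions and nothing more:

* **Flight path.** Straight out at 1.05 m/s, a 0.35 s raised-cosine
  180° heading ramp at ~0.51 m/s, then a return leg aimed at a point
  just in front of the perch center, decelerating with distance to
  0.6 m/s (approach speeds stay near 1 m/s until shortly before
  touchdown).  The trial ends at the last complete wingbeat boundary
  once the bird reaches the approach point, so the wingbeat-rate
  channels tile the recording exactly.  Body yaw is the path tangent.
* **Head yaw.** A staircase of raised-cosine velocity bumps.  By
  default one candidate saccade per turn-phase wingbeat at 75% of the
  downstroke, kept with probability 0.8 (about 4–5 saccades per flight,
  matching the observed rate), amplitudes drawn around 30° and rescaled
  to sum to the turn angle, so the head is rotationally stabilized
  between saccades; durations follow the amplitude-duration line
  duration_ms = (amplitude + 14)/1.5, i.e. a 1500 °/s average speed.
  The raised-cosine profile has zero velocity and acceleration at its
  endpoints and gives analytic amplitude (peak·duration/2), peak
  velocity and supra-threshold span, so recovery tests use the
  generator's own closed forms, never the detector.
* **Wingbeats.** Beats drawn sequentially; per phase a beat is
  intermittent with probability 0.28/0.12/0.35 (before/during/after the
  turn, reflecting the observed tendencies), frequencies N(17.0, 0.8)
  vs N(9.5, 0.5) Hz and stroke ratios N(1.35, 0.11) vs N(0.53, 0.06).
  Stroke instants are quantized to the 2000 Hz frame grid, as
  frame-counted annotations are.
* **Perch.** Fore-aft swing with 0.05 m half-amplitude (~10 cm
  peak-to-peak excursion; the reported "amplitude ~10 cm" does not
  disambiguate, and peak-to-peak was chosen), 0.005 m sideways, 1.33 s
  period (a pendulum of the perch's hanging length), random phase per
  trial.
* **Noise.** I.i.d. Gaussian on every observed marker coordinate with
  a 3-D RMS of 1.3 mm (per-axis σ = 1.3/√3 mm).  With the 16 mm head
  marker separation this yields ≈3.8° raw yaw error, matching the
  reported orientation error.  Noise enters positions, not derived
  angles, as in the real pipeline.
* **Cohorts.** Out/return speeds scaled by N(1, 0.12) per trial,
  random perch phase, per-trial seeds from a spawned seed sequence,
  trials assigned round-robin to five synthetic birds.

What the generator does **not** emulate: aerodynamics, wing-induced
visual-field occlusion (saccade/wingbeat phase coordination is tested
purely on timing), 3-D wing kinematics beyond the wingtip elevations
needed for stroke amplitude and segmentation, eye-in-head movements,
tracking dropouts and manual-tracking bias (noise is white), and any
behavioral variability beyond the randomized schedules above.  Passing
recovery tests therefore demonstrates correctness of the algorithms
under the stated statistical structure, not performance on real video
data.

## Numerical choices and degenerate inputs

* Sparse-channel gaps are interpolated by the smoother's penalty
  (weight 0), never by ad-hoc interpolation.
* λ = 0 with gaps is an error (nothing constrains the gap values).
* Coincident head markers raise an error naming the frame.
* Duplicate timestamps, >1% sample-interval jitter and illegal
  stroke-mark orders are rejected at validation.
* A beat exactly at the frequency separator is labeled normal (≥ rule).
* The c.v. is masked where the across-trial mean is ~0; the
  most-parsimonious decision uses the window-mean c.v. and requires the
  parameter to be defined over the whole window.
* EM non-convergence after 2000 iterations raises with the fit trace;
  zero-variance samples are rejected before fitting.

## Problem sizes in the test suite

The default suites run a 16-trial cohort at 2000 Hz (≈1.5 s per trial,
~350 wingbeats, ~70 saccades) for parameter recovery, 1000 random
400-sample velocity traces for the detector-oracle equivalence, and
200-point series for the leave-one-out smoother oracle.  These sizes
keep the full suite under ten seconds while leaving every statistical
margin (mode separation, label accuracy, histogram peaks) far from its
tolerance.

## Known limitations

* The amplitude-duration slope recovered from noisy cohorts runs ~15%
  above the generating 1500 °/s because the boundary-extension floor
  compresses measured durations proportionally to saccade length; the
  fitted r ≈ 0.88 mirrors realistic scatter.
* Body yaw is interpolated from ~4 samples per wingbeat; head-body
  difference angles inherit the body channel's ~10 Hz bandwidth.
* The turn-segmentation rule is heading-based and assumes the bird
  translates during the turn; a pure pirouette would defeat it.
* `flight_filters` covers only the kinematically observable inclusion
  criteria.
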