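# Methods

## The measurement model

A head undergoing a closed-head impact is treated as a rigid body
moving in the sagittal plane, observed through two markers fixed to
its helmet and tracked in high-speed video at 3230 frames/s. Each
marker is annotated manually several times per video (annotation
repeats); the per-frame arithmetic mean of the repeats is the track
used for analysis, which suppresses annotation noise by
1/sqrt(n_repeats). Coordinates are right-handed and y-up with
counter-clockwise-positive angles; files recorded in the image
convention (y down) are flipped on ingestion.

Linear kinematics of the head centre are the component-wise average
of the two markers' central-difference velocities and accelerations.
For two symmetric markers this vector average is exactly the centre
motion of the rigid body; a configuration switch
(`average_vectors=False`) instead averages the per-marker speed and
acceleration magnitudes, an alternative reading of "average of each
tracking point" that differs whenever the markers move in different
directions. Linear acceleration is reported both in m/s² and in units
of standard gravity (g = 9.80665 m/s², exact division).

Planar angular velocity comes from the rigid-body velocity relations
between the two markers,

    V1x = V2x − ω ΔY
    V1y = V2y + ω ΔX,        [ΔX, ΔY] = p1 − p2.

The squared error of these two equations is quadratic in ω, so the
least-squares estimate is closed-form:

    ω = (ΔX (V1y − V2y) − ΔY (V1x − V2x)) / (ΔX² + ΔY²).

To reduce noise the residuals are stacked over three successive
frames (each with its own per-frame Δ, six residuals, equal weights)
and a single ω minimizes the stacked sum; this is the default series
estimator, again closed-form. The closed forms are verified in the
test suite against a brute-force one-dimensional minimization of the
stated residuals (grid scan plus parabolic-vertex refinement, exact
for a quadratic objective) on over a thousand random instances.

Angular acceleration is a three-point central difference of ω. On
the reporting path ω is first low-pass filtered (Butterworth, 10 Hz
cutoff, order 4, zero-phase forward–backward). Peak angular
acceleration is reported to one significant digit (half-away-from-
zero rounding) in acknowledgement of the digital filtering.

### Filtering scope and the 10 Hz caveat

A 10 Hz cutoff at 3230 frames/s attenuates millisecond-scale events
by orders of magnitude, which is difficult to reconcile with peak
angular accelerations occurring ~2.5 ms after impact. The pipeline
therefore (a) applies the filter only on the angular-acceleration
path — peak angular velocity is extracted from the raw ω series
unless `filter_omega_for_peaks` is set — and (b) always records the
unfiltered angular-acceleration series (`alpha_unfiltered`)
alongside the filtered one. Cutoff, order and phase behaviour are
all configurable; no intent beyond the stated 10 Hz Butterworth is
guessed.

## Peaks, phases, curve fits

Peaks are maxima of magnitude with ties broken by earliest time; the
search excludes one sample at each end by default
(`peak_edge_exclusion`) because endpoints use one-sided differences.

Phase segmentation is threshold-based on |ω|: the linear
(translation) phase ends when |ω| first exceeds a configurable
fraction (default 20%) of its peak; the primary rotation ends at the
first subsequent local minimum of |ω| below that threshold, the
hand-off to the slow secondary rotation; the remainder is the
secondary rotation. A recording with no angular excursion is flagged
degenerate with boundaries at zero.

Descriptive curve fits per phase segment use least-squares cubic
polynomials by default (`model="polyK"` selects the degree); for
linear velocity and acceleration the rise (up to the peak) and decay
(after the peak) are fit separately. Constant segments collapse to a
constant-term fit. The functional family is a package choice — the
fits are reporting/visualization aids and never feed peak
extraction.

## Impact energy and human-equivalent scaling

Impact energy is the piston's kinetic energy, E = ½ m v² with
m = 0.05 kg; the measured calibration velocities 8.13 and 9.10 m/s
give 1.652 and 2.070 J, reported to one decimal as the 1.7 J and
2.1 J energy levels. `batch_energy_check` summarizes a set of
calibration impacts (per-impact energy, mean, coefficient of
variation, pass/fail against a nominal ± tolerance band).

Equal stress–equal velocity scaling converts rodent kinematics to
human-equivalent values with the cube-root brain-mass ratio 13.8:
angular velocity is divided by the factor, angular acceleration by
its square, and linear velocity is not scaled. The source
description of this procedure is internally contradictory (the
factor is first said to apply to linear and angular velocity, then
linear velocity is said to be unscaled); the package follows the
explicit later statement and leaves linear acceleration unscaled as
well, with every exponent configurable in `ScalingRule`. Scaled
summaries carry a provenance string naming the rule and refuse to be
scaled twice.

## Group statistics

Cohort summaries report, per peak metric, the mean, SEM
(sample sd / sqrt(n), n−1 denominator) and coefficient of variation
(100 · sample sd / mean). Sample statistics use the n−1 denominator
throughout, the usual convention at small n. Group membership comes
from the energy label in the metadata, never inferred from the data.
No inferential statistics between groups are computed.

## The synthetic-data generator

The generator prescribes (it does not simulate the mechanics of) a
three-phase sagittal head motion and projects it onto noisy marker
tracks:

1. **Vertical translation** (default 1.5 ms): a raised-cosine
   vertical acceleration pulse of amplitude 1.371 × 10⁴ m/s²
   (~1400 g), followed by a deceleration pulse over the primary-
   rotation window that brings the centre to rest. Peak centre speed
   is amplitude × duration / 2 ≈ 10.3 m/s at the end of phase 1.
2. **Primary rotation** (nominal 2 ms window): angular velocity
   rises fast to 80% of its 200 rad/s peak over the first half of
   the window (`omega_onset_fraction`), then approaches the peak
   gradually until `omega_peak_time` (default 5 ms — the observed
   peak timing of such impacts, which falls after the nominal
   primary window), then decays over `omega_decay_duration`
   (default 5 ms) to the slow secondary rate.
3. **Secondary rotation** (default 200 ms, measured from the decay's
   end): a constant plateau rate followed by a raised-cosine stop
   pulse (default 50 ms). The plateau rate is solved in closed form
   so the orientation change over this phase equals
   `secondary_rotation_total` (default 175° = 3.054 rad) exactly.

All channels are sums of raised-cosine acceleration pulses, chosen
because they are C¹-continuous (zero value and slope at the pulse
edges) and have closed-form velocity and displacement integrals, so
the generated series carry exact analytic ground truth. Markers are
projected as `centre + R(θ)·offset` with default body-frame offsets
(±5 mm, 0) — a 10 mm separation placeholder, configurable, since the
true helmet marker separation is not documented. Annotation noise is
iid Gaussian per coordinate per annotation repeat (default 3
repeats), the simplest model consistent with independent manual
isolations; its magnitude is configurable and zero by default.

The generator emulates the phase structure, sampling rate, noise and
repeat structure of real recordings. It does **not** emulate piston
or neck compliance (motion is prescribed, not emergent), 3D or
out-of-plane motion, marker occlusion or dropped frames, tracker
systematic error, or per-animal anatomical variability. Passing
recovery tests therefore demonstrate that the estimator chain is
correct and adequately conditioned at the stated frame rate and
noise level — not that real-video peaks are unbiased, which depends
on how sharp the true transients are relative to the 3230 frames/s
grid.

### Resolution of fast transients

Central differences average the true velocity over ±1 frame, and the
three-frame ω window widens the effective smoothing kernel to about
±2 frames (~0.6 ms). Transients narrower than a few frames are
therefore systematically under-read: the default 1.5 ms linear-
acceleration pulse spans ~5 frames and its recovered peak reads
~25% low, which is why peak-acceleration accuracy is not a recovery
criterion. The angular-velocity peak, by contrast, is broad
(~3.5 ms rise, 5 ms fall) and recovers to well within 1% noiselessly;
peak times recover to within 2 frames, and the trapezoidal integral
of estimated ω over the recovered secondary segment matches the
configured 175° within 1%. With 10⁻⁴ m annotation noise and
triplicate averaging, the peak ω error stays within 10% in ≥90% of
seeded replicates. These numbers are computed by the test suite and
`scripts/acceptance.py`, not asserted.

## Numerical and interface choices

* Differentiation: interior `(x[i+1] − x[i−1]) / 2dt`, one-sided
  first differences at the endpoints; missing frames are an error,
  never interpolated, because differentiation assumes uniform
  sampling and silent interpolation would bias accelerations.
* Calibration: scale = known separation / median per-frame pixel
  separation (median for robustness to annotation outliers), applied
  uniformly to both axes; idempotent on calibrated data.
* Repeat averaging sorts repeats by id before summing, so the result
  is bit-identical under input reordering.
* Filtering uses `scipy.signal` second-order sections with
  forward–backward application; zero-phase filtering preserves peak
  timing, which is part of what is reported.
* Seeds: the pipeline derives per-animal seeds from the root seed
  via `numpy.random.SeedSequence`, records them in the run log with
  parameter values and SHA-256 digests of written track files, and
  re-runs are byte-identical.
* Problem sizes in the test suite and acceptance script (default
  0.21 s recordings at 3230 frames/s ≈ 680 frames, 20-replicate
  noise studies, 9-animal simulated cohorts, 10³ oracle instances)
  were chosen to exercise every code path at the study's native
  sampling rate while keeping a full run in the seconds range.

## Known limitations

* 2D only; out-of-plane motion of real heads projects into the
  tracked plane and is not modelled.
* The angular-velocity estimator assumes exact rigidity; helmet
  compliance appears as correlated noise it cannot distinguish from
  rotation.
* The default 10 Hz angular-acceleration path is faithful to the
  stated processing but, as noted, suppresses millisecond transients;
  users interested in transient α should read `alpha_unfiltered` or
  raise the cutoff.
* Phase segmentation is threshold-based and intended for motions
  with a clear primary-rotation excursion; oscillatory ω traces may
  need a custom threshold.
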