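# Methods

This note records the models implemented, the defaults chosen where the
underlying assays leave parameters open, what the synthetic data do and
do not emulate, and the numerical conventions. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## Looming model

An object of radius *r* approaching at constant speed *v* subtends
θ(t) = 2 tan⁻¹((r/v)/t) at *t* ms before contact; the profile depends on
r/v alone. The stimulus starts at an onset angle and saturates at a
fixed maximum. Neither the onset size nor the final size is a measured
quantity here, so both are configuration defaults, not claims:
θ_onset = 10° and θ_max = 90° (a conventional looming endpoint). The
hypothetical contact time is onset time plus (r/v)/tan(θ_onset/2).
Clock convention: t = 0 at stimulus onset; contact is reported both as
an absolute clock time and as a countdown. Angles are handled in
radians internally and reported in degrees.

## Attack kinematics

Each coordinate axis of each labelled point is smoothed with a
Butterworth low-pass filter applied forward–backward (zero phase),
followed by a Savitzky–Golay polynomial filter. Orders and cutoffs are
not dictated by the assay, so the defaults are the standard choice for
1 kHz animal kinematics and are fully configurable: Butterworth order 2,
cutoff 50 Hz; Savitzky–Golay window 11 frames, polynomial order 3.

Differentiation is by central differences on the filtered positions;
speed is the velocity norm, and acceleration is the derivative of scalar
speed (matching scalar attack-speed panels) rather than the
vector-acceleration magnitude; the alternative is a one-line switch.
Gaps of at most 5 frames are linearly interpolated before filtering;
longer gaps abort the event with an instruction to split it — a gap is
never silently zero-filled.

The attack window starts at the first frame after the last sustained
hover (speed below 0.02 m s⁻¹ for at least 50 ms) and ends at the
contact-or-escape frame, which defines t = 0; times are in ms, negative
before the end. With no detectable hover the full series is used and
flagged. Peak metrics are maxima over the window; ties in peak speed
break to the latest frame.

Angles use a prey-centered frame anchored at the fly centroid at the
attack-window start (configurable to per-frame fly position): +X is the
mesh-wall normal into the chamber, +Z up. Elevation is
atan2(ΔZ, ‖ΔXY‖); azimuth is the angle of (ΔX, |ΔY|) from +X, folding
only the lateral coordinate so the full [0°, 180°] range (front to
back) remains distinguishable. The fly's body axis is not used — it is
unresolvable from a single centroid. "Mean" angles are arithmetic means
over the window (not path-length-weighted; the distinction is small for
near-straight approaches). The retinal angular size at the end of the
event is θ = 2 tan⁻¹(r/d) with 2r the damselfly head width; the default
head width of 2.2 mm is a configuration value derived from the
correspondence of the ~40° activation threshold with a ~3 mm approach
distance, not a measured constant, and is never hard-coded in the
computations.

## Ethograms and mode classification

Durations run from wing raise to leg lift-off. Classification against
the fixed 7 ms boundary is strict: short iff duration < boundary, with
equality assigned to long — the modes are defined by strict
inequalities, and assigning ties to long is conservative for short-mode
claims. The data-driven boundary estimator fits a two-component
Gaussian mixture to log-durations (positive, right-skewed) with 10 EM
restarts at tolerance 1e-8 and a fixed seed, and returns the
posterior-equality point between the component means, located on a
dense grid with linear interpolation of the sign change. Degenerate
fits are rejected on two grounds: component mean ratio below 1.3, or no
density dip between the component means (a unimodal sample split into
halves produces two overlapping components with no dip). The fixed
7 ms boundary remains the default classifier; the mixture estimate is a
check.

When pooling across stimulus speeds, an optional seeded downsampling
utility equalizes group sizes so neither speed dominates.

## Competition statistics

WCB and PCI are computed exactly as printed count ratios; trials in
which no fly of either group was eaten have an undefined index and are
excluded with a logged count. Index means are tested against zero with
a one-sample Student *t*; a zero-variance sample returns p = 1 at the
null mean and p = 0 otherwise. Group contrasts use the equal-variance
Student form (Welch by flag). Wilson score intervals come from the
closed form, with the degenerate proportions pinned to exact 0/1
endpoints. Tukey HSD adjusted p-values use the studentized-range
distribution on the pooled mean square error; the implementation is
cross-checked against statsmodels' Tukey HSD in the test suite. The
slow/fast speed-split threshold is an input parameter (the 0.167 m s⁻¹
value used in example configurations is a dataset-derived constant, not
a model constant).

A note on Wilson coverage: at n = 30 the interval's true coverage
oscillates with p because the binomial is discrete; at p = 0.1 or 0.9
the exact coverage is 97.4% (the k = 6 lower bound sits at 0.0951), and
no procedure-faithful implementation can land within ±2 percentage
points of nominal there. The test suite documents this as an expected
failure of that band at the extreme proportions; coverage at p = 0.5 is
95.7%.

## Synthetic data

The generators emulate the statistical structure the analyses assume,
with programmed ground truth for parameter recovery:

- **Attacks**: the prey sits at the origin; the damselfly head hovers
  40 mm away (100 ms, 0.05 mm positional jitter) and then darts along a
  straight approach. The constant profile moves at the programmed speed
  throughout. The accelerating profile cruises at 30% of peak and then
  executes a terminal burst — a raised-cosine speed bump, symmetric
  about its maximum, peaking exactly the programmed time (default
  30 ms) before the end and relaxing back to cruise speed at contact.
  The symmetry is deliberate: a profile that holds its maximum until
  contact, or peaks asymmetrically, makes the peak time unidentifiable
  or biased after zero-phase smoothing, whereas a locally symmetric peak
  survives linear-phase filtering unmoved. Approaches truncate at an
  end distance: 4 mm for escapes (just beyond the ~3 mm grab range
  implied by the 40° threshold) and, in the study-shaped scenario,
  3.2 mm for captures of GF-intact flies versus 1.5 mm for captures of
  GF-silenced flies — silencing lets the predator close past the
  threshold before the grab. Digitization error is i.i.d. Gaussian per
  coordinate per frame (default σ = 0.1 mm); real tracking error is
  autocorrelated, a documented simplification.
- **Ethograms**: Bernoulli take-off; Gaussian reaction time; mode drawn
  by genotype weight; duration log-normal per mode (modes near 4 ms and
  15 ms straddling the 7 ms boundary); escape time = reaction +
  duration.
- **Trials**: eaten counts binomial per group per trial (100 flies per
  group, 10 predators per chamber as metadata).

One scenario seed fans out to independent substreams per data stream
via `numpy.random.SeedSequence.spawn`; identical seeds give
bit-identical outputs.

Two scenarios ship in `configs/`. `null_scenario` has no genotype
effect anywhere. `paper_shaped` encodes the qualitative effect
signature at realistic scale: 60 attacks per arm with log-normal peak
speeds (median 0.15 m s⁻¹, bracketing the 0.167 m s⁻¹ reference mean);
capture probability logistic in peak speed with a genotype offset
(GF-intact flies escape nearly all slow attacks; silenced flies are
captured at any speed, halving their escape proportion); ethogram
cohorts of 80 vs 29 flies with short-mode weights 0.7 vs 0.02 and
identical reaction-time distributions (mean 60 ms, sd 6 ms — fast-loom
latencies are tightly stimulus-locked, and this spread makes the
escape-time contrast reliably detectable at these cohort sizes); eight
competition trials at consumption probabilities 0.30 vs 0.15 (expected
index ⅓). What passing these scenario tests shows is that the pipeline
detects effects of this designed size and shape — not that real
videography would yield these numbers.

## Problem sizes

Test and scenario sizes are chosen to keep every property measurable at
desk scale: 50-event batches for recovery statistics, 10⁴ replicates
for type-I-error calibration (vectorized for the studentized-range
battery, with the packaged test verified decision-by-decision against
the vectorized computation on 300 replicates), 500–2000 samples for
mixture-boundary recovery.

## Known limitations

- No camera calibration or 2D→3D reconstruction: input is already-
  digitized 3D points.
- The generator's straight-line attacks cannot probe curvature-dependent
  errors in the angle computations.
- Scenario effect sizes are plausibility-scaled, not fitted to any
  dataset; distributional summaries from real videography (attack-speed
  distributions, angle histograms) are emulated only to first order.
- The azimuth reference is the wall normal, not the fly's heading; with
  real flies the two differ by the fly's orientation on the mesh.
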