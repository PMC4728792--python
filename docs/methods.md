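# Methods

This note documents the models, parameter choices and numerical decisions behind
`gazekit`, in the spirit of a methods appendix: what each stage assumes, which knobs
matter, what the synthetic sessions do and do not emulate, and the known limitations.

## Problem setting

A remote monocular eye tracker reports the gaze point-of-regard (POR) as Cartesian
coordinates in a *horizontal* stimulus plane (a robotic/virtual-reality workspace where
stimuli appear among the hands). Because stimulus depth varies across such a plane,
the scalar visual-angle conversion used by frontal-screen trackers
(tan(β/2) = a/2b at fixed viewing distance b) misstates ocular kinematics, and fixed
classification thresholds tuned for reading-distance screens misbehave. `gazekit`
instead

1. lifts the planar POR into an eye-centred frame and converts to spherical
   coordinates,
2. differentiates there to obtain true angular velocity and acceleration of the eye,
3. fits a two-component lognormal mixture to the local velocity peaks of each session
   and derives a participant- and task-specific saccade velocity threshold, and
4. classifies smooth pursuits, saccades and fixations with rules that combine ocular
   kinematics, stimulus kinematics, and a distance-dependent foveal tolerance.

## Coordinate transforms and kinematics

With the eye at height H above the plane and head orientation R (identity when
untilted), a POR (x, y) maps to the eye frame as `[x';y';z'] = [0;0;H] + R·[x;y;0]`,
then to spherical (ρ, θ, ϕ) with θ the full-quadrant azimuth in [0, 2π) and ϕ the
angle from the downward Z' axis. Ocular pitch and yaw follow as α = ϕ and
γ = 90° − θ; the two rotation-matrix decompositions (about Z' by 90°−θ then X' by ϕ,
versus yaw-then-pitch) agree element-wise under this substitution, which the tests
verify to 1e-12. Roll is left implicit (Listing's law: pitch and yaw determine it),
and no vergence output is produced for this monocular geometry.

Cartesian derivatives come from Savitzky–Golay smoothing differentiation
(default window 21 ms rounded to an odd sample count, polynomial order 2 — short
enough to preserve saccade peaks at 500 Hz). The spherical rates use the closed
forms

    ϕ̇ = [z'(x'ẋ' + y'ẏ') − (x'²+y'²)ż'] / [ρ²√(x'²+y'²)]
    θ̇ = (x'ẏ' − y'ẋ') / (x'²+y'²)

(the θ̇ numerator is the derivative of the full-quadrant azimuth; the tests check
both rates against a 10 kHz finite-difference oracle on analytic trajectories).
Angular speed is v = √((θ̇ sinϕ)² + ϕ̇²), reported in deg/s; the acceleration
magnitude uses the transverse spherical acceleration components, with second
derivatives obtained by re-applying the same Savitzky–Golay derivative to the
first-derivative series.

The foveal visual radius FVR = ρ·tan(δ/2)/sin(ε) projects a foveal cone of
half-angle δ/2 (δ defaults to 3° plus the session's mean calibration error) onto the
plane; ε = arcsin(z'/ρ) is the gaze-to-plane angle, exact for an untilted head and
documented as approximate otherwise. FVR grows with viewing distance and obliquity
and provides the classifier's spatial tolerance.

## Preprocessing

Blinks are sentinel-coded runs (default −100); screen outliers are samples outside a
configurable workspace rectangle; one-sample spikes deviate from both (mutually
consistent) neighbours by more than five times the running median sample-to-sample
step. Blink and outlier gaps, widened by a 20 ms margin on each side (pupil-size
distortion brackets full occlusion), are bridged with a cubic spline fitted to the
five valid samples flanking each side; spikes take the closer neighbour's value.
All coordinates are then low-pass filtered at 20 Hz with a second-order Butterworth
applied forward–backward — zero phase, so event onsets are not delayed. Repaired
samples are flagged invalid, are labelled `blink` by the classifier, and are excluded
from threshold fitting and every event rule.

## Adaptive saccade threshold

Local maxima of v are extracted with a 50 ms minimum separation and a prominence
floor of max(2×MAD(v), 3.5 deg/s). Both values matter more than they look:
zero-phase filtering leaves small velocity transients (a few percent of the peak
velocity) on each flank of every saccade, and at short separations these form a
spurious narrow mode in the peak distribution; the absolute floor keeps the
sensor-noise velocity ripple (≈2 deg/s) out of quiet sessions. Peak speeds are
bimodal on the log scale — a slow mode from drift, microsaccades and (in dynamic
tasks) pursuit, and a fast mode from saccades — and a two-component Gaussian mixture
on log speeds is fitted by EM (maximum likelihood). EM runs from four deterministic
percentile-pair initialisations and keeps the best likelihood; a single start is
prone to inferior local optima on multimodal peak data. The saccade velocity
threshold is the symmetric log-scale decision point

    v_thr = exp[0.5·((μ₂ − 2σ₂) + (μ₁ + 2σ₁))]

and the acceleration threshold stays at the literature value 6000 deg/s². Because
pursuit peaks populate the slow mode, the fitted threshold is higher in
pursuit-rich tasks than in fixation/saccade tasks — the task dependence that makes
fixed thresholds unreliable in this setting. With a flat (unimodal) peak
distribution the formula still evaluates, with a warning; single-session fits on a
few hundred peaks carry real sampling variability (human analogues span tens of
deg/s), which is why the acceptance script reports medians over three sessions.

## Event classification

Saccades: velocity peaks above v_thr are delimited by the flanking local minima of v
(onset is the first sample after the pre-peak minimum, offset the last before the
post-peak minimum — the minima belong to the neighbouring events, a convention that
makes noiseless boundaries exact to ±1 sample); a candidate is confirmed if its peak
acceleration exceeds the acceleration threshold and its duration at least 5 ms.
Overlapping candidates merge; extents are clipped so they never run into blink or
pursuit samples.

Static tasks then label fixations: maximal sub-threshold runs whose POR stays within
FVR + T_R of a displayed static stimulus (T_R the stimulus' circumscribing radius)
for at least 40 ms, bound to the nearest qualifying target. Without target
information, a velocity-plus-dispersion fallback is used and flagged.

Dynamic tasks classify pursuits first (fixations being rare when everything moves),
then saccades, then fixations. A pursuit requires, continuously for ≥40 ms and for
one target: ‖G−T‖ ≤ (1+η)(FVR+T_R); |v − Ṫ| ≤ η·max(Ṫ, 10 deg/s); v < v_thr; and
v̇ < a_thr, where Ṫ is the target's angular speed through the identical
transform-and-differentiation pipeline and η (default 0.2) is the noise-tolerance
coefficient. The 10 deg/s floor guards the relative tolerance against nearly static
targets. Gaze may lag or lead the target within the spatial tolerance. Within
100 ms of each saccade offset, a fixation is opened at the first unclaimed sample
where the bound target is pulling away from stationary gaze (Ṫ > η·v and T̈ > η·v̇)
and closed at the first violation; it is kept if it lasts ≥40 ms and the convex hull
of its gaze points stays within η·π·FVR² of the starting foveal circle. Everything
else is unclassified. Events are inclusive intervals, pairwise disjoint, and cover
the sample axis together with the unclassified filler.

A fixed-threshold comparator (0.3° displacement, 30 deg/s, 8000 deg/s²; two classes
only) reproduces the behaviour of commercial parsers: slow pursuits fall below its
velocity threshold and are labelled fixations.

## Scoring

For each event class, the quantitative score (FQnS/SQnS/SPQnS) is the percentage of
reference samples of that class the candidate also assigns to it, averaged over
trials; the misclassification index counts reference samples the candidate assigns
to a *different* oculomotor class (unclassified and blink samples reduce the overlap
but are not misclassification). Counting is inclusive: a reference fixation spanning
samples 201–800 contributes 600 samples, and a candidate covering 191–750 recovers
550 of them. Event-level sensitivity/precision matches events by majority overlap of
the shorter event, which is robust to the boundary smearing that zero-phase
filtering makes inevitable.

## Synthetic sessions

The generator assembles gaze in direction space and projects it onto the plane by
intersecting the gaze ray with it (the analytic inverse of the forward transform,
exact to round-off). Two scenario families emulate the tasks this instrumentation is
used for: a *static* visual-search session (25 scattered stimuli visited twice,
fixations of 250–450 ms linked by saccades) and a *dynamic* session of 32 trials —
fixation circle, then two objects approaching the participant at 24–42 cm/s, one of
which is foveated by a primary saccade, held briefly, caught up with, and pursued
for 350–800 ms. A matched variant with identical trial and saccade structure but
motionless objects provides the controlled fixation/saccade-only comparison for the
task-dependence of the threshold.

Saccades follow a minimum-jerk angular profile with durations from the main-sequence
duration law D = 21 ms + 2.2 ms/° · A (peak velocity 1.875·A/D, saturating with
amplitude), per-saccade duration scatter of 12 % (log-normal), and landing errors of
8 % of amplitude (capped at 0.8°). Saccades to moving objects are programmed from a
retinal snapshot with 10 % undershoot, so catch-up saccades of a few degrees follow
the ~100 ms pursuit-onset lag; saccade–pursuit transitions are velocity-continuous
minimum-jerk blends between the departure and arrival paths.

The noise model is deliberately physiological rather than spectrally flat:

- slow oculomotor drift, band-limited below 0.5 Hz with a slowly varying lognormal
  amplitude envelope, carries most of the configured positional RMS (default 0.3°);
  its velocity content is a few deg/s, as for real drift — a 0.3° process
  band-limited at the pipeline's 20 Hz passband would instead have ~20 deg/s
  velocity RMS, which no pursuit rule could tolerate and no eye produces;
- white measurement noise of 0.05° RMS (video-tracker class);
- explicit microsaccades during holds (rate 2.5 /s, lognormal amplitudes with median
  0.3°, clipped at 1.2°), labelled as part of the fixation; their velocity peaks
  populate the slow mixture mode, as microsaccades do in real recordings;
- during pursuit: a positional lag (|N(0.9°, 0.7°)|, capped at 3.5°, leading in 20 %
  of segments) with slow wander, plus a multiplicative gain fluctuation of 8 % of
  target speed at 1.2–2.5 Hz — proportional ripple stays inside the η·Ṫ matching
  tolerance at every speed while producing realistic intermediate velocity peaks;
  generic drift is reduced to 20 % while the pursuit loop is closed on the target.

Blinks are injected as sentinel-coded gaps of 80–200 ms (0.1 /s) and corneal-reflection
spikes as single displaced samples (0.2 /s). All randomness flows through one seeded
generator; a fixed seed reproduces the session byte-for-byte.

What passing tests on these sessions show — and what they do not: the generator
emulates the *statistical structure* the method assumes (main-sequence saccades, a
broad lognormal slow velocity mode, pursuit with physiological lag and gain noise,
task geometry of a transverse workspace). It does not model oculomotor-plant
dynamics, glissades, head motion, vergence, nonstationary calibration error, or
nonlinear target motion, so recovery scores here bound what clean recordings of
these tasks could yield, not what any recording will.

## Known limitations and numerical notes

- Small saccades and the acceleration gate: a 20 Hz zero-phase low-pass attenuates
  the acceleration of a 25–35 ms saccade several-fold, so catch-up saccades below
  ≈4° fall under the fixed 6000 deg/s² confirmation threshold and cannot be
  detected. In dynamic sessions this caps event-level saccade sensitivity near 0.8
  even though sample-weighted SQnS stays ≈90; the static task, whose saccades are all
  larger, reaches sensitivity ≈1. This is a property of the rule set, not of the
  implementation.
- Boundary smearing: filtering and Savitzky–Golay smoothing delocalise event onsets
  by roughly half the smoothing window. Detected saccade extents therefore
  legitimately overrun instantaneous ground-truth transitions; noiseless boundary
  recovery is verified with a minimal 3-sample differentiation window, where it is
  exact to ±1 sample.
- Pursuit of static targets: the velocity-match floor (η·10 deg/s) lets quiet gaze
  near a static target register as pursuit when η is large; this is the mechanism by
  which fixation misclassification grows with η, mirroring the sensitivity analysis
  of the tolerance coefficient.
- Degenerate mixtures: if the fitted components overlap (μ₁+2σ₁ ≥ μ₂−2σ₂) the
  threshold formula is still applied, with a warning. Single-session threshold fits
  are noisy; pool trials (the generator's sessions already pool 32) and prefer
  medians across sessions for reporting.
- Time is milliseconds and positions metres throughout; angles are radians
  internally and degrees at every interface; event intervals are inclusive at both
  ends and durations are (offset − onset + 1)/rate.
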