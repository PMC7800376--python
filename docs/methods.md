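# Methods

This note documents the models implemented in `obstride`, the assumptions of
the synthetic-data generator, and the numerical choices made where the
design was genuinely open. All positions are millimetres, speeds m/s, and
frames are 0-based at 250 Hz (4 ms per frame) unless stated otherwise.

## The analysis chain

**Tracking QC.** Five steps are applied in a fixed order per landmark per
view: (1) frames with tracking confidence below 0.99 are masked; (2) frames
that violate a velocity constraint are masked — implemented as a spike
detector that requires a displacement above 15 mm/frame both into and out of
the frame while the two-frame displacement bridging it stays below the
threshold, so genuine fast swing motion (which moves on rather than
returning) is untouched; (3) a 3-frame temporal median filter; (4) frames
whose x position disagrees between the two views by more than 5 mm are
masked (x is the shared axis); (5) masked values are linearly interpolated.
The two views are merged into 3D (top view → x, z; bottom view → x, y;
shared x averaged). A landmark with more than 50 % of frames masked fails QC
with an error. Note the median filter is not a no-op even on clean data: it
clips sharp trajectory corners (swing-end reversals) by up to a few mm and
is only approximately idempotent there; the tests bound rather than forbid
this.

**Un-head-fixing.** World-frame x is camera x plus the wheel displacement
from the rotary encoder; y and z are unchanged, and the obstacle becomes
stationary within a trial. The inverse transform restores the original
arrays exactly (the camera-frame positions are retained).

**Stance and steps.** A paw is in stance when its horizontal velocity is
within 0.2 m/s of the wheel's (equivalently, world-frame speed ≤ 0.2 m/s —
both accessors are provided) *and* its height is within 5 mm of the wheel
surface; the binary trace is debounced with a 20 ms (5-frame) median. Each
maximal swing interval is one step: lift-off at the first swing frame,
touch-down at the first stance frame after it, length = world-frame
touch-down x minus lift-off x, peak height = max z during swing. Control
steps are the two latest steps of a paw completed before whisker contact.
Hildebrand rasters resample every limb's stance indicator onto a 100-bin
phase grid defined by the reference limb's stride (left hind by default) and
average across strides; the row mean of each limb approximates its duty
factor. A trial succeeds when total paw–obstacle contact (summed across
paws, overlaps merged within a paw) is at most 20 ms, read inclusively;
per-paw success requires zero contact. The 20 ms threshold is applied to the
summed-across-paws total, with per-paw totals also reported, since the
wording of the rule is ambiguous between the two.

**Predicted landing distance and labels.** Per session and paw, ordinary
least squares of control-step length on mean wheel speed during the step
gives `L̂ = â + b̂·v`; the in-sample mean absolute error of the implied
landing positions is reported (a 5-fold held-out variant is available).
For the forepaw in swing at contact,
`Δpred = (lift-off x + â + b̂·v) − x_obstacle`, negative meaning the paw
would land in front of the obstacle. A trial is *unmodified* (excluded from
model fitting) iff the paw lands in front of the obstacle and within
±2.5 mm of the predicted landing position; otherwise the sign of
(actual − predicted) labels it shortened or lengthened. Steps over the
obstacle are never unmodified. Trials where both forepaws are in swing, or
both in stance, at contact are excluded.

**Decision model.** A logistic model (scikit-learn, effectively
unregularized at C = 10⁴) predicts lengthen vs shorten from eight features
measured at whisker contact: obstacle horizontal position (relative to the
nose) and height, the swing paw's horizontal and vertical position and
velocity, wheel velocity, and body angle. Features are z-scored within
mouse (a raw-scale option is retained), classes are weighted by inverse
frequency, and accuracy is the unweighted mean over stratified, seeded
15-fold cross-validation — stratification is our choice, made because
per-mouse class counts are small. Forward selection greedily adds the
feature with the greatest mean across-mice accuracy gain, ties broken by the
canonical feature order. Shuffled baselines permute labels and refit under
the same protocol. A single-hidden-layer (100-unit) network benchmark under
the same protocol is provided but is not part of the core pipeline.

**Matched trials.** For manipulation comparisons, control and manipulated
trials of one mouse are paired by Euclidean distance in z-scored (wheel
velocity, body angle, tail height at contact) space; pairs are selected
greedily from the smallest distance, each trial used once, until 20 % of
the smaller condition is retained. An optimal-assignment variant
(`scipy.optimize.linear_sum_assignment`) is available behind a flag.

**Reaction time.** For each trial the paw's trajectory — (x, z)
displacement since lift-off, optionally extended a fixed horizon past the
landing into the next stride — is compared to the mean of the 40 control
steps whose pre-contact window (swing onset to contact) is nearest in the
same coordinates. The per-frame deviation from the family mean, divided by
the per-frame family SD (floored at 0.1 mm) and combined across coordinates
by the Euclidean norm, must exceed 2.5 for two consecutive frames at or
after contact; the first such frame defines the latency. Requiring two
frames rejects single-frame noise; "mid-swing" trials are those with
contact in the central 60 % of the swing. Leave-one-out validation on
control steps (predicting the penultimate step from earlier ones) estimates
the false-onset rate. Time-to-contact fits a least-squares line to the
anterior-most paw position over the 100 frames before contact, with time
zero at contact, and extrapolates to the obstacle position; non-approaching
fits are flagged `None`.

**Contact consensus.** Each stride-1 window of 10 frames yields an 11-class
probability vector (first contact at relative position 1–10, 1-based, or
not present). Every window casts one hard vote for the frame at
`start + argmax − 1` unless "not present" wins; the frame with the most
votes is the contact frame, ties resolving to the earliest frame (a
first-contact detector should not bias late). A soft-vote variant
accumulates probability mass instead.

## The synthetic-data generator

The generator exists so every estimator above can be scored against ground
truth. Its defaults are the study conditions of the behaviour it emulates;
each can be overridden.

**Gait.** A global stride clock advances at the per-stride speed; diagonal
limb pairs (LF+RH, RF+LH) share phase and the two pairs are antiphase, with
duty factor 0.6. Per-stride speed is an AR(1) process with marginal mean
0.55 m/s and SD 0.10 m/s; the AR coefficient 0.9 makes running speed drift
on a ~2 s timescale, which is what bouts of wheel running look like, while
still letting a session sample the whole speed range. Step length obeys the
planted law `L = a + b·v + ε` with a = −3.7 mm, b = 107 mm/(m/s) and
ε ~ N(0, 6.9²); with these values the speed–length correlation is
`b·σ_v / √((b·σ_v)² + σ_ε²) ≈ 0.84` and the expected absolute residual is
`σ_ε·√(2/π) = 5.50 mm`, so the pipeline's calibration statistics emerge from
first principles rather than tuning. Body-relative landing placement is a
stationary AR(1) chain (marginal SD 12 mm) whose stride-to-stride increments
*are* the residuals ε — this pins the chain's autocorrelation at
`1 − σ_ε²/(2·σ_pl²) ≈ 0.83` and keeps the length law exact while giving
realistic placement variability. Swing trajectories are a half-cosine in x
and a half-sine in z with apex 9 mm scaled by predicted step length; the
step-length residual accrues late in swing (weight `((u−0.5)/0.5)₊²`),
consistent with motor noise accumulating during execution. Mean forepaw
landing sits 10 mm behind the nose, hind paws 45 mm; nose, tail and body
angle are smooth AR(1) nuisance processes, and all view coordinates carry
0.25 mm tracking jitter.

**Trials.** Obstacles engage after 0.9, 2.7 and 4.5 m of each 5.4 m reward
cycle (each jittered ±0.1 m), start 0.31 ± 0.015 m ahead of the nose, have
heights uniform on [4, 10] mm, 3.175 mm diameter, and are lit on a random
half of trials. Whisker contact occurs when the obstacle reaches
`15 mm + 25.2·(v − 0.55) + N(0, 9²)` anterior of the nose; the slope/noise
pair realizes the contact-position–speed correlation of 0.27, and the 15 mm
reach is a stated, overridable default. Steps whose swing crosses the
obstacle get their apex raised to the obstacle height plus ~5 mm clearance,
planting the paw-height/obstacle-height correlation.

**Decision rule.** On each contact trial the forepaw in swing is lengthened
with probability `σ((Δpred − θ − c·h)/τ)`, θ = −10 mm, c = 1 mm per mm of
obstacle height, so lengthening is favoured when the paw would land close
to or beyond the obstacle and disfavoured for high obstacles. Far-in-front
trials are sometimes left unmodified (probability decaying as Δpred
approaches the obstacle), and unmodified steps land within ±2 mm of their
prediction — the behavioural reading being that near-obstacle placement is
under fine control. The temperature τ defaults to the value at which the
Monte-Carlo Bayes accuracy of the rule — evaluated on the distribution of
trials that survive the exclusion rules, since that is the population any
model is scored on — equals 0.73; bisection with a 400 000-trial Monte Carlo
gives τ ≈ 10.0 mm. The feature-model spreads (placement SD 12 mm, contact
noise 9 mm) were chosen so that, under this rule, the obstacle and paw
horizontal positions carry the most decision information, matching the
behaviour's known feature-importance structure. Shortened steps land
≥ 3 mm short of (and at least 6 mm in front of) the obstacle; lengthened
steps land ≥ 3 mm beyond the prediction, usually clearing the obstacle.

**Reaction latency.** The decision acts on the trajectory starting
`planted_latency` (default 24 ms) after contact, and the frame at
contact + latency is the *first frame that departs* from the unmodified
continuation. If the paw is still airborne with ≥ 2 frames of flight left,
the correction ramps in with immediate velocity and completes within
~16 ms, scaled by the controllable time remaining; a braking paw may stall
but never moves backwards, and shortened steps descend from the onset.
Because the default swing lasts only ~40 ms, onsets later than the landing
are expressed instead as an early lift of the paw's *next* step toward the
decided landing ("carry-over"); when even that cannot happen by the planted
time, the ground truth records the realized first-departure frame rather
than contact + latency. The trial-level cohort generator
(`generate_decision_trials`) mirrors the same feature model analytically —
one row per trial rather than a kinematic trace — which is what makes
temperature calibration and 20-mouse cohorts cheap; the frame-level and
trial-level paths are cross-checked against each other in the tests.

**Artifacts.** `inject_tracking_artifacts` corrupts a clean session at
configurable per-frame rates: confidence drops below 0.99, ±30 mm
single-frame jumps, ±8 mm top-vs-bottom x disagreements, and 1–4-frame
gaps; the injection log and clean arrays are kept for recovery scoring.

**Randomness.** One root seed; the gait, noise, per-trial decision and
artifact streams are derived from it with fixed offsets, so trial k is
invariant to the number of trials and a (config, seed) pair is
bit-reproducible.

## What the simulator does and does not show

Passing tests demonstrate that each estimator recovers what the generator
plants at realistic noise levels — segmentation is frame-accurate, the
landing model recovers (a, b), the GLM recovers the planted threshold and
weight directions, consensus voting recovers planted contact frames, and
median latency estimates recover 12/24/40 ms planted latencies. They do not
certify performance on real video-derived tracking, where failure modes are
correlated in time, gaits are less stereotyped, obstacle steps reorganize
the following strides, and the decision process is richer than a
single-threshold logistic rule. Two known idealizations matter when
interpreting numbers: contact features are measured noiselessly apart from
tracking jitter, and the cross-validated decision accuracy sits 2–4 points
below the calibrated Bayes accuracy (≈ 70 % vs 73 %) because the linear
model cannot fully reconstruct the hidden lift-off position from the eight
contact-time features and because 15-fold CV on ~160 trials per mouse pays
a finite-sample cost.

## Problem sizes and tolerances

The shipped verification uses 53 sessions of 50 trials (~40 000 frames
each) for the gait calibration, a cohort of 20 mice × 3 sessions × 72
trials (~160 modeled trials per mouse) for the decision model, ≥ 200
analysable trials per planted latency for reaction recovery, and 500
streams for consensus recovery. Bisection tolerances: temperature
calibration to ±0.005 in accuracy; logistic fits run to scikit-learn's
default convergence at C = 10⁴. Degenerate inputs are defined throughout:
empty stance traces yield empty step tables, fewer than two control steps
warn, single-class decision datasets raise, non-approaching time-to-contact
fits return `None`, and an all-"not present" consensus stream returns a
flagged empty result.
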