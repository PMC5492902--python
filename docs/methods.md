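# Methods

`armfuse` re-implements a family of magnetic-inertial (mIMU) upper-limb
motion trackers and the protocol used to compare them, replacing the
optical-capture laboratory recordings of the original evaluation with a
synthetic generator whose forward models are the very measurement equations
the trackers invert. This note records the models, conventions, parameter
choices and their limits.

## Kinematic model

The arm is a serial chain rooted in the chest, which is treated as a steady
rigid body fixed at the root frame origin (x anterior, y subject-left,
z up). The shoulder is a spherical joint whose centre lies 4.5 cm below the
acromion along the vertical; the forearm adds elbow flexion/extension and
pronation/supination, for five functional degrees of freedom:
`q = [SFE, SAA, SIR, EFE, EPS]`. At the N-pose (all angles zero) every
segment frame coincides with the root frame and the arm hangs vertically,
so the wrist sits at `shoulder + (0, 0, −(L_ua + L_fa))`. Default segment
lengths are anthropometric-scale fixtures: upper arm 0.30 m, forearm
0.25 m, acromion at (0, 0.20, 0.25) m. Axis signs are chosen so each named
functional movement actuates exactly one coordinate with an intuitive
positive direction (flexion forward, abduction lateral).

A seven-row Denavit–Hartenberg (classic, distal convention) variant of the
chain is generated programmatically: two clavicle rows (protraction about
z, elevation about x, frozen at zero by default) precede the five arm
rows. The generator solves each row's twist and angle offset so the row z
axes coincide with the joint axes at the reference pose, and attaches fixed
alignment transforms that restore the original segment frames; forward
kinematics and all propagated rates of the two parametrizations agree to
machine precision (asserted in the test suite). The chain-UKF runs on this
DH form; because both clavicle rows are frozen its state covers the same
five angles as the EKF's.

Angular velocity, angular acceleration and linear acceleration are
propagated down the chain by an exact frame-to-frame recursion (documented
in `arm_model.py`), not by numerical differentiation; finite differences of
the forward kinematics serve only as the independent oracle in tests. The
per-segment linear-acceleration tree uses the **parent's** angular rates
for each rigid inter-segment offset — the printed recursion subscripts are
frame-ambiguous, and the parent-rate reading is the one consistent with
differentiating the forward kinematics (verified against second central
differences).

## Synthetic study conditions

The generator scripts one functional movement per sequence:
`q(t) = A·sin⁴(πφ(t))`, with phase advancing one unit per cycle — 7 slow
cycles (2 s period) followed by 2 fast cycles (1 s), after a 1 s static
N-pose lead-in; total 17 s at 100 Hz. `sin⁴` has vanishing value, velocity
and acceleration at every cycle boundary, so mixed-period schedules remain
twice continuously differentiable and cycle boundaries fall at exact
scripted instants (cycle segmentation therefore reads the script's phase
rather than detecting peaks). Default amplitudes are 90° at the elbow and
60° for shoulder movements. The lead-in doubles as the N-pose reference
hold used by the evaluation alignment and gives the filters a settled
start.

Sensor models (per segment, mid-segment lever arms by default, identity
mounting rotations unless perturbed):

- accelerometer: specific force `R_mountᵀ R_segᵀ (a_point − g₀)` with
  `g₀ = (0,0,−9.81) m/s²` and the lever-arm terms `α×r + ω×(ω×r)` included;
- gyroscope: body rate plus a constant bias (random direction, fixed
  magnitude) and white noise;
- magnetometer: the normalized field `m₀ = (cos 60°, 0, −sin 60°)`
  (dip-angle-like inclination) rotated into the sensor frame, optionally
  offset by a scripted time-varying disturbance;
- camera: normalized (intrinsics-free) perspective coordinates of the
  wrist from a chest-fixed camera pitched 45° down, at 1/8 of the IMU rate
  (12.5 Hz). Samples behind the camera (depth < 1 cm) or beyond |u| = 3
  normalized units are emitted as NaN — marker loss — and skipped by the
  camera-aided filter. The field-of-view cutoff is this package's
  extension: a chest camera cannot keep the wrist in view at large
  shoulder elevations, and clamping visibility is more honest than
  feeding off-axis bearings no real detector would produce.

Default noise (gyro σ 0.005 rad/s, bias 0.01 rad/s, accel σ 0.05 m/s²,
mag σ 0.01, camera σ 0.005) is commodity-mIMU-scale; the study the
generator emulates did not publish sensor specifications. All randomness
flows from one integer seed; identical seeds give byte-identical streams.

What the generator does **not** emulate: soft-tissue artefact, sensor
scale-factor/misalignment errors, hard/soft-iron distortions, marker
occlusion dynamics, time misalignment between modalities, and anatomical
joint-centre uncertainty. Passing tests therefore demonstrate correctness
of the estimators against their own modelling assumptions and the relative
behaviour of the families, not field accuracy on human recordings.

## Trackers

All trackers ingest the same streams; the free-segment ones (1, 2, 3) run
per limb and reconstruct the wrist by composing estimated attitudes with
the known chain offsets, the chain-constrained ones (4, 5) estimate joint
angles directly.

1. **Vector KF + QUEST** — per-segment KF on the 6-vector `[g; m]`
   expressed in the sensor frame, propagated with the gyroscope as control
   input through `I₆ + T·blkdiag(−S(ω̃), −S(ω̃))` and corrected with the
   identity measurement model; the filtered pair feeds the Davenport
   q-method against the N-pose references. The propagation sign is the
   body-frame transport theorem (`v̇ = −ω×v`), fixed empirically against
   the simulator.
2. **EKF with angular-velocity decay** — state `[ω; q]`; the angular
   velocity decays exponentially (shared default time constant
   `t_k = 0.5 s`, per-axis configurable) and the quaternion propagates
   bilinearly; the state is propagated as `(Φ(X)T + I₇)X` while the
   covariance uses the full Jacobian of the bilinear block. Measurements
   are the gyroscope and the QUEST fix, hemisphere-aligned to the
   prediction before the innovation.
3. **Complementary filter** — `q⁺ = q_p + (q_m − q_p)/k` with `q_p` the
   first-order gyro propagation and `q_m` the QUEST fix. The blend is
   componentwise and not norm-preserving, so the output is renormalized
   and `q_m` is hemisphere-aligned first; without both the filter diverges
   at attitude sign flips. The *perfect* variant subtracts the
   chain-propagated linear acceleration at the sensor point before the
   QUEST fix; in the tracking harness this is computed online from the
   filter bank's own attitude estimates, gyro rates, and
   backward-differenced gyro for angular acceleration — no ground truth
   enters the tracker.
4. **Chain EKF** — state `[q, q̇, q̈]` per joint with the exact
   constant-angular-acceleration block; measurements are the chain-predicted
   accelerometer/gyroscope, the magnetometer reduced to a scalar heading
   (yaw of the measured field rotated to the root with the state's
   attitude, compared to the reference field's heading, innovation
   wrapped), and the camera bearing at its own rate. The observation
   matrix is built by central finite differences (step 1e-6) of the
   measurement function, evaluated in one batched kinematics pass; camera
   rows with lost markers or negative predicted depth are dropped for that
   step. The trunk filter of the original three-filter cascade is omitted:
   the chest is fixed by the protocol.
5. **Chain UKF** — same state and process on the DH chain; the nine-axis
   measurement model (lever-arm accelerometer, full three-axis
   magnetometer) passes through the unscented transformation
   (Merwe scaling, α = 1e-3, β = 2, κ = 0). Sigma points are redrawn after
   the additive process noise so it enters the measurement statistics;
   covariance factorization failures escalate through jitter before
   raising. With a linear measurement function the update reproduces the
   closed-form Kalman update (asserted in tests with α = 1).

A gyro-only strapdown integrator (first QUEST fix, then pure first-order
integration) is the negative control: under gyro bias its attitude error
grows linearly and every fused method must beat it.

### Parameter defaults and tuning

The source evaluation states only that parameters were chosen to optimize
each method; no values are printed. Defaults here were fixed once by a
coarse grid search over the three comparison movements at the full protocol
length, balancing the noise-free and default-noise regimes, and are
config-exposed:

- CF gain `k = 300` (correction time constant `k·T = 3 s`; small gains make
  the filter measurement-dominated and acceleration-corrupted, large gains
  approach strapdown and inherit its bias drift — the noisy-regime error
  over the movement set is U-shaped in `k` with its minimum near 300;
  tuning on sequences shorter than the correction time constant hides the
  bias floor, so the grid must run at protocol length),
- method 1: process driven by an assumed 0.01 rad/s gyro error;
  accelerometer measurement σ 1.0 m/s² (dominated by unmodelled linear
  acceleration, not sensor noise), magnetometer 0.05,
- method 2: `t_k = 0.5 s`, rate measurement σ 0.01 rad/s, attitude
  measurement σ 0.3 (the QUEST fix degrades under acceleration),
- chain filters: white-jerk PSD 200 rad/s³, accel σ 0.07 m/s², gyro σ
  0.01 rad/s, heading σ 0.05 rad, mag σ 0.02, camera σ 0.01, and an
  N-pose prior (σ: 0.1 rad, 0.5 rad/s, 5 rad/s²). Trajectories start at
  the N-pose with zero rates, so the zero initial state is consistent;
  the free-segment filters initialize from the first QUEST fix.

## Evaluation protocol

Estimated and reference wrist trajectories are first translated so their
N-pose reference samples (the mean over the lead-in hold) coincide, then
the estimate is rotated onto the reference by the proper orthogonal
Procrustes solution (SVD with determinant correction; reflections
excluded). The original description writes the minimization and the
application of the rotation in inconsistent directions; this package
implements the only reading under which the aligned estimate is comparable
to the reference. Because a constant frame rotation is absorbed, the
accuracy index underestimates each method's absolute error — it is a fair
comparative measure, and is documented and tested as such.

Indices: `E` is the mean per-sample Euclidean distance in millimetres;
`C` is the Pearson correlation computed per axis on centered coordinates
and averaged over axes whose reference variance is non-negligible (a
single-DoF movement leaves signal-free axes whose correlation is
meaningless noise; per-axis values are retained in the report, and a
zero-variance reference makes `C` undefined — reported as NaN). Whether
the original correlation was computed on positions, per axis, or on joint
angles is not stated; this choice is the package's own.

The cross-method run covers EFE, SFE and SAA, each at the full
7-slow + 2-fast schedule (17 s with the lead-in); EFE feeds the per-cycle
table. Batch checks use 20 seeds in the test suite and 8 in the acceptance
script.

## Numerical choices and degenerate inputs

- Quaternions are scalar-first Hamilton; `q` and `−q` are one rotation and
  every comparison is hemisphere-aware. Conversions delegate to
  `scipy.spatial.transform`.
- Quaternion integration is the first-order `(q + T·q̇)/‖·‖` update,
  matching the discrete `(ΦT + I)` filter forms; an exact axis-angle
  exponential is available behind a flag.
- The Wahba solver is the Davenport q-method (largest eigenvector of the
  4×4 profile matrix); collinear observation sets raise a degeneracy
  error. The SVD Procrustes solver is retained as an independent oracle
  and never used by the trackers.
- Covariances are symmetrized every step and checked for positive
  semi-definiteness; the EKF update uses the Joseph form; the UKF
  escalates Cholesky jitter over bounded retries.
- A magnetic reference parallel to gravity makes attitude unobservable and
  is rejected at synthesis time.
- Tight "recovers exactly" tests use the Frobenius metric
  `‖R₁−R₂‖_F = 2√2·sin(θ/2)` rather than `arccos`-based angles, whose
  precision floor is ~1e-8.

## Known limitations

- The evaluation model fixes the chest: trunk tracking and two-arm runs
  are out of scope.
- The heading reduction is the standard tilt-compensated compass; with an
  inclined field its first-order invariance holds for pitch-like attitude
  perturbations, not for roll about the field's horizontal axis — the
  camera channel is the designed remedy under field disturbances.
- The camera model is intrinsics-free by construction; image processing,
  distortion and rolling shutter are not modelled.
- Scapulohumeral-rhythm coupling of the shoulder girdle is not modelled;
  the clavicle rows exist in the DH chain but stay frozen.
- Reported accuracies are comparative (post-alignment) on synthetic data
  and are expected to be optimistic relative to optical-capture studies of
  real arms.
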