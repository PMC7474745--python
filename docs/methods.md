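# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic study does and does not establish.

## Physical model and assumptions

The upper limb with its locked-elbow orthosis is treated as one rigid body
rotating about a fixed shoulder center (an ideal ball-and-socket joint).
Motion is slow enough to be quasi-static: inertial and centrifugal terms
are neglected, and velocity-dependent viscous resistance is minimised by
the slow protocol rather than modelled. A quasi-static gate flags samples
whose flange speed exceeds 0.1 m/s (configurable) so violations are
visible rather than silently averaged in.

Force/moment balance of the limb: the shoulder reaction `(F_s, M_s)`, the
robot assist wrench `(F_R, M_R)` at the flange, limb gravity `G`, and the
moments `M_G`, `M_FR` of gravity and assist force about the center satisfy
`F_s + F_R + G = 0` and `M_s + M_R + M_G + M_FR = 0`. The passive torque
is defined as the lumped `M_P = M_s + M_G = −M_R − M_FR`; the package does
not attempt to decompose it, since only the lump is observable without
inertial parameters of the subject.

Because the rigid flange connection over-determines the statics, the true
split between `F_s` and `F_R` is unknowable from the wrench alone. `M_P`
as computed is invariant to that split: it equals the moment of the
limb-applied flange wrench about the center, whatever the force split.
The synthetic generator fixes one convention (the robot carries the full
limb weight, `F_s = 0`) purely so its ground truth is well defined.

Sign convention: a recovered wrench is the action of the environment
(limb + orthosis) on the flange; the robot's assist wrench is its
reaction. The vendor-reported moment is assumed to act about the flange
origin.

## Robot model

The arm is a generic 7-revolute chain defined entirely by configuration
(per-joint link translation, local rotation axis, flange offset). The
shipped *default model* uses alternating z/y axes with vertical offsets
0.36 / 0.42 / 0.40 m and a 0.126 m flange plate — published-style
lightweight-arm geometry, not a claim about any specific robot. The world
frame is right-handed with Z up; the seated subject's coronal, sagittal
and vertical body axes are taken parallel to world X, Y, Z. Angles are
radians everywhere except the CLI boundary (degrees).

Wrench recovery solves `Jᵀ f = τ_e` by Moore–Penrose pseudo-inverse (SVD,
relative cutoff 1e-10): deterministic, exact when `τ_e` lies in the column
space of `Jᵀ`, minimum-norm least-squares otherwise, and graceful near
singular configurations (rank < 6 attaches a warning and flag).

## Shoulder kinematics

* **Sphere fit**: algebraic (Coope-style) linear least squares — the
  sphere equation is linearised in the center and a radius carrier and
  solved in one pass. Closed-form and deterministic; the iterative
  geometric fit appears only as an independent oracle in the tests.
  Fewer than 4 points or a coplanar configuration raises a
  degenerate-geometry error.
* **Former-part rule**: the center tends to translate near the end of the
  range of motion, so by default the first 70% of each run feeds the fit
  (no number is standard; 0.7 is configurable and validated by the
  center-drift scenario, where including the end stage inflates the rms
  residual).
* **Calibration**: at the reference pose all shoulder angles are zero
  (upper arm hanging vertically), so the shoulder center sits directly
  above the manually measured elbow landmark at the fitted radius and the
  shoulder frame is world-aligned. This fixes the constant
  flange-to-shoulder transform; `T_s = T_F ·(flange→shoulder)` thereafter.
  The reconstruction is validated by round trip on synthetic scenes.
* **Globographic angles**: elevation is measured from the downward
  vertical (−Z), the plane of elevation is the azimuth about Z from world
  X (the coronal axis). The datum is a declared convention. At the poles
  the azimuth is undefined and reported as 0 with an explicit degeneracy
  flag — deliberately avoiding the gimbal artifacts of Euler-sequence
  descriptions. Axial rotation of the upper arm is excluded by
  construction (a direction on a sphere has no roll).

## Statics processing

The moving-average filter (default 25 samples = 0.5 s at 50 Hz) is applied
to the external joint torques *before* wrench recovery; the window is
centered with symmetric edge shrinking so constants are preserved at the
boundaries. 0.5 s suppresses sensor noise without distorting the slow
passive motion; the Dirichlet-kernel gain of the filter is unit-tested.
Orthosis gravity (pre-measured mass and center of mass in flange
coordinates) is subtracted as a force at the rotated center of mass.

Repeatability: each trajectory is recorded twice; runs are resampled onto
a common elevation grid and compared by the rms torque difference
normalized by the combined torque range. The default tolerance is 0.1
(10% of range — "significant difference" is inherently a protocol choice);
failing pairs abort the pipeline as invalid data.

## Network and training

A three-layer feedforward network, 2 inputs → H hidden → 3 outputs, all
sigmoid. Inputs and targets are min-max normalized to (0.05, 0.95) rather
than (0, 1): a sigmoid cannot attain its endpoints, so normalizing onto
the open interval keeps every target reachable. Constant dimensions map
to the midpoint with a pinned inverse.

Training is full-batch Levenberg–Marquardt: the residual Jacobian is
assembled analytically by backpropagation (verified against finite
differences at 1e-5), each step solves `(JᵀJ + μI) δ = Jᵀr`, `μ` shrinks
×0.1 on accepted steps and grows ×10 on rejections (μ₀ = 1e-3,
μ_max = 1e10 — conventional damping defaults). Stopping: normalized MSE
goal 0.001, epoch cap 1000, or `μ` exceeding its ceiling. The goal is
evaluated on the normalized scale, where 0.001 is meaningful. A learning
rate of 0.01 is recorded in the configuration for fidelity but is inert:
LM has no learning-rate parameter. Weights are initialized with a seeded
Nguyen–Widrow-style scheme (random hidden-row directions, magnitudes
tiling the normalized input box, spread biases); the (seed, data, config)
triple determines the trained model bit-for-bit. Whether inputs and
outputs should share a normalization interval is not fixed by the method;
both normalizers are independently configurable.

H = 9 is the default: in the hidden-unit sweep (5–20) it reliably reaches
the goal in a few tens of epochs without excess capacity.

## Evaluation protocol

All runs are pooled; 500 samples are drawn uniformly without replacement
(seeded) for training and the remainder is scored. Per world axis: MAV of
the true torques, MSE of the prediction, RE = MSE/MAV. As defined, RE
carries units of N·m (MSE is quadratic, MAV linear); it is kept as the
protocol defines it rather than converted to an RMSE ratio, and the MAV
in the denominator is that of the *true* torques. Text output rounds to
3 decimals; JSON stores full precision.

## Synthetic data: what it emulates, and what it does not

The generator renders a rigid limb (default 3.5 kg, center of mass 0.28 m
from the shoulder — adult-male upper-limb scale) on a fixed center, with
an upper-arm (shoulder-to-elbow) radius of 0.30 m, dragged along a
monotone elevation ramp 10°–120° at 50 Hz in the 0° and 30° planes of
elevation with a ±3° low-frequency "secondary movement" wander, plus iid
Gaussian torque-sensor noise (σ = 0.05 N·m per joint). Robot-level logs
solve damped least-squares inverse kinematics (pose error < 1e-8,
minimal joint motion from the previous sample) and apply `τ_e = Jᵀf`.
Every rendered sample satisfies the quasi-static balances to ≤ 1e-10 by
construction.

The passive torque field is limb gravity about the center plus an elastic
resistance that is zero at the neutral hanging posture, stiffens
progressively (linear + cubic terms), rises steeply near the 125° range
limit (exponential edge, 0.14 rad scale), and carries a bounded
engagement undulation (1.0 N·m about the elevation axis and 0.8 N·m about
the vertical, 25° period, smooth onset envelope) of the kind that
sequential capsuloligamentous engagement and orthosis-tissue interaction
superpose on real torque-angle curves. A linear restoring term
(2 N·m/rad) acts about the vertical against out-of-plane drift. The
undulation amplitudes were chosen so the field's capacity demand sits in
the intended window for the hidden-unit sweep — a 5-unit network
underfits the 0.001 goal while 9 units reach it — while held-out RE stays
at the few-percent level; magnitudes were chosen to span the several-N·m
scale of measured shoulder passive torques, and none are claimed to be a
specific subject's values.

What passing tests on this generator shows: the estimation chain is exact
on noiseless logs, degrades gracefully and linearly with sensor noise,
and the network protocol recovers a field of realistic scale and
smoothness from 500 samples. What it does not show: robustness to
scapulothoracic motion (the fixed-center assumption is built into the
generator as well as the estimator), soft-tissue artifact, residual
muscle activity, velocity-dependent resistance, or robot dynamic-model
error in `τ_e` — on real data these appear as structured bias the
synthetic study cannot expose.

## Numerical choices and degenerate inputs

* Pseudo-inverse cutoff 1e-10·σ_max; singular configurations warn and flag
  rather than raise.
* Sphere fits reject < 4 or coplanar points; radial projection rejects the
  center point (undefined direction).
* Pole postures report azimuth 0 with a degeneracy flag.
* The LM inner loop re-solves with inflated μ on a failed Cholesky/solve;
  non-finite losses raise a training-divergence error carrying the partial
  history.
* Moving-average windows must be odd so the filter is symmetric and
  unbiased for linear trends in the interior.

## Problem sizes

The standard study uses two trajectories of 562 and 561 samples (matching
the protocol's pooled 1123), two repeats each; the full pipeline including
rendering runs in ~10 s and the 10-seed × {5, 9} hidden-unit sweep in
~20 s on one CPU. Unit tests use 30–200-sample runs, which suffice for the
round-trip tolerances tested.

## Known limitations

* The calibration's placement of the shoulder center relies on the
  vertical-reference-pose assumption; a tilted reference biases the
  center by `radius·sin(tilt)`.
* RE inherits MSE's unit quirk (see above); compare RE values only
  between fields of similar magnitude.
* The estimator treats the flange-to-shoulder transform as constant; real
  orthoses creep.
* `repeatability_check` compares along elevation only; trajectories that
  revisit the same elevation in different planes need a 2-D comparison
  grid.
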