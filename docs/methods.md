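# Methods

This note documents the model, the estimation procedure, the numerical
choices and the known limitations of `armoc`, at the level of detail a
user needs to judge what the package's results do and do not establish.

## Plant model

The arm is a planar serial chain of three rigid, frictionless links with
revolute joints (shoulder, elbow, wrist), the shoulder fixed at the origin
of an inertial frame.  Joint angles follow a relative convention: θ₁ is
measured from the downward vertical (hanging rest = 0), θ₂ and θ₃ relative
to the proximal segment, flexion positive; angles are kept unwrapped.

The equations of motion are written in closed form.  In absolute link
angles φ = Lθ (L lower-triangular ones) the chain has the classic n-link
pendulum structure

    M_abs(φ)_jk = I_j δ_jk + β_jk cos(φ_j − φ_k),
    bias_j      = Σ_k β_jk sin(φ_j − φ_k) ω̄_k² + g w_j sin φ_j,

with β = aᵀ diag(m) a and w = m a built from the lever-arm matrix a of the
segment centres of mass; mapping by L gives the relative-coordinate form
M(x) dx/dt = r(x, c) used throughout.  An independent symbolic derivation
(Lagrange's equations via `sympy.physics.mechanics`) is kept in the test
suite as a second route to the same dynamics; the two agree to 1e-9.

**Anthropometry.** Only segment lengths are measured from data.  Masses
default to the standard fractions of body mass (2.8 % / 1.6 % / 0.6 % for
upper arm / forearm / hand), centres of mass to 43.6 % / 43.0 % / 50.6 %
of segment length from the proximal joint, and inertias to uniform rods —
all overridable in the YAML config.  Defaults correspond to a 70 kg
subject with segments 0.30 / 0.26 / 0.08 m.

**Joint ranges.** A C∞ sigmoid torque (logistic in the angle, steepness
30 rad⁻¹, scale 5 N m) opposes excursion beyond each joint's range
(shoulder −60…200°, elbow 0…150°, wrist −70…80°).  It is essentially zero
strictly inside the range.  The equilibrium-holding torque compensates it,
and its analytic slope is included in the linearization so that the linear
model is the exact Jacobian of the simulated plant — this matters because
the default elbow target (0°, full extension) sits on a range boundary
where the sigmoid's slope is not negligible.

**Linearization point.** The target posture of the flexion task — arm
raised, θ = (180°, 0°, 0°), a gravitationally unstable equilibrium — with
the gravity-and-constraint-compensating torque c\*.  Control is applied
about it: c = c\* − K(x − x\*).  The linearization is analytic: at the
equilibrium the forcing vanishes, so A's velocity rows are
M⁻¹(∂τ_limit/∂θ − ∂g/∂θ) and B's are M⁻¹; a frictionless chain has no
velocity feedback in A.

**Integration.** Stiff-capable variable-step solvers (LSODA) at
rtol 1e-8 / atol 1e-10 for trajectories of record (candidate evaluations
in the fit use 1e-6 / 1e-8).  With the fitted weight magnitudes (~10⁷) the
closed loop has poles from ≈−1.2 s⁻¹ (the movement) to ≈−10⁷ s⁻¹; linear
closed-loop trajectories are therefore evaluated through the
eigendecomposition of A − BK (exact at the sample times, immune to
stiffness), and quadratic costs by adaptive integration of an augmented
ODE, never by fixed-step quadrature of the fast transient.  A
numba-compiled right-hand side (algebraically identical to the numpy one,
asserted to 1e-14 in the tests) accelerates the thousands of nonlinear
candidate simulations of a fit; everything falls back to the generic
solver when numba is unavailable.

## Cost functional and controller

J = ∫₀^∞ (xᵀZx + cᵀUc) dt with Z = diag(θ_p·1₃, ω_p·1₃) and U = I₃,
states taken as deviations from x\*.  The infinite horizon reflects the
untimed task; in practice the closed loop decays exponentially and
simulated horizons of 10–40 s make the tail negligible.  The stabilizing
Riccati solution comes from a Schur-form solver
(`scipy.linalg.solve_continuous_are`); the residual is verified below
1e-8·(1+‖S‖) and closed-loop stability is asserted.  Only the ratio
θ_p : ω_p : 1 (the unit control penalty) shapes K — scaling Z and U
together leaves the gain unchanged, which the tests assert.  θ_p and ω_p
are treated as dimensionless weights; their ~10⁷ magnitudes relative to
the unit torque penalty are part of the parameterization, not a physical
unit statement.

## Inverse estimation

Per subject: segment lengths are averaged over the initial 5 s static
window of the *raw* 30 fps frames (the Fourier-resampled series carries a
small rectified interpolation ripple that would bias lengths by ~0.2 mm —
enough to matter, see below); the recording is spectrally resampled
30→60 fps; markers are projected on the sagittal plane (vertical = +y,
horizontal = dominant wrist-displacement direction, sign chosen so flexion
is positive, which also mirrors left/right arms); joint angles and the
wrist's vertical displacement are extracted.  Start and target postures
are medians of the angle series around the movement onset and end, using
only even-index samples (spectral upsampling preserves the original frames
exactly; the interpolated half-frames carry one-sided edge ringing), with
an Aitken-Δ² extrapolation of the exponential approach for movements that
have not fully settled by the end of the record.

The error of a candidate (θ_p, ω_p) is the ℓ₂ norm of the difference in
wrist vertical displacement over the movement window.  Crucially, the
simulated candidate is pushed through the *same* processing as the data —
rendered at 30 fps, Fourier-resampled, re-baselined — so that the
resampling artefacts of a finite record are common to both sides of the
comparison and cancel.  The search runs over (log₁₀θ_p, log₁₀ω_p) with
Nelder–Mead (bounds [3, 9], start (6, 6), unit initial spread, three
restarts), since linear-space search at ~10⁷ magnitudes is hopelessly
ill-conditioned.

Two deliberate extensions of the plain two-parameter search:

1. **Onset nuisance parameter.**  The movement onset is known only to a
   frame or two from thresholding, yet the trajectory error is sensitive
   to ~2 ms shifts, which would otherwise bias the weights.  A sub-frame
   onset estimate (square-root-of-excursion extrapolation) seeds a third
   search parameter, bounded to ±0.25 s.

2. **Magnitude profiling.**  The trajectory *shape* pins the ratio
   θ_p/ω_p and the onset sharply, but the common magnitude
   √(θ_p ω_p) moves the wrist trajectory only through the plant's gravity
   nonlinearity (a ~0.4 % effect at these gains): the error surface is a
   long, shallow, curved valley.  The default (`plant="hybrid"`) therefore
   refines the magnitude by minimizing the *profiled* error — for each
   magnitude, the error minimized over ratio and onset — on the nonlinear
   plant, with a coarse scan over the fitted decades followed by a
   bracketed 1-D minimization and a small simplex polish.  On noiseless
   synthetic recordings this recovers both weights to a few percent.

**Identifiability under noise.**  With realistic marker noise (5 mm) the
gravity signature that identifies the magnitude is obliterated: across
noise seeds the fitted magnitude wanders by orders of magnitude while the
ratio stays within a few percent.  For cohort work the estimator therefore
offers `magnitude="pinned"`, which fixes √(θ_p ω_p) at a reference scale
(10⁷, the scale of the group functionals) and estimates the ratio — the
standard resolution for an unidentifiable parameter combination.  Fitted
per-subject weights in pinned mode are reference-scaled quantities: their
*between-group differences* are meaningful (both group tests are then
carried by the well-identified ratio), their absolute magnitudes are a
convention.  Group comparisons in this package's own benchmarks use pinned
fits; per-subject magnitude estimates should only be trusted for very
clean data.

Failures of individual candidates (ill-conditioned Riccati solves at
extreme weight ratios, diverged simulations) receive a large penalty so
the simplex moves away; a fit where *every* candidate fails raises.
Fits are deterministic given the input and the optimizer seed.

## Stiffness analysis

τ = Kx splits as τ = K₁x₁ + K₂x₂ into angle and velocity feedback.  The
velocity direction of maximal resistance solves max_{‖x₂‖=1} ‖K₂x₂‖; since
K₂ is in general not symmetric, the exact maximizer is the leading right
singular vector of K₂ (τ\* the leading singular value), computed by SVD;
the eigen-spectrum of K₂ is reported alongside for the symmetric reading,
where the two coincide.  For the group presets the two controllers share
x₂\* to within hundredths of a degree while τ\* differs (≈3053 N m healthy
vs ≈2291 N m patient): the patient controller resists velocity less.

## Perturbation response and time-frequency analysis

Oscillatory disturbance of the neural state estimate is modelled by
feeding the controller x_n = x + κ·cos(γt)·**1** (the same scalar sinusoid
added to all six states; κ = 0.2 by default).  On the linear plant the
response has a closed form (modal homogeneous part plus the particular
sinusoid), used for speed; the numerically integrated route is kept and
checked against the closed-form frequency response in the tests.

Signals are analysed with a pseudo-Wigner–Ville distribution: the analytic
signal's lag kernel z(t+τ/2)·z̄(t−τ/2), tapered with an odd triangular lag
window (127 samples) and Fourier-transformed over the lag.  The triangular
(Fejér-kernel) window keeps monochromatic ridges nonnegative, so clipping
the residual interference when accumulating energy loses only the edge
truncation residue (<1 % on a 60 s record); the unclipped map retains
exact energy marginals (the total integral equals Σx²/fs by
construction).  The frequency grid reaches Nyquist (30 Hz at 60 fps) with
~0.24 Hz spacing; perturbation frequencies above Nyquist excite the loop
physically but appear aliased in the sampled response — sweep abscissae
label the input γ, not a resolvable response bin.

The cumulative energy E(t_max, f_max) is the trapezoidal double integral
of the (clipped) map; the frequency sweep normalizes E over the γ list by
its maximum.  The default analysed signal is the *demeaned wrist vertical
displacement*: the loop's displacement response rolls off above the slow
pole (≈0.2 Hz), producing the characteristic low-frequency dominance of
the response curve, whereas the velocity response of these very stiff
loops is nearly flat in γ (available via `signal="wrist_vy"`).  Default
window: 60 s at 60 fps, f_max = Nyquist.

## Synthetic data

`generate_recording` simulates the nonlinear closed loop at the true
weights from hanging rest to the raised target (10 s at 60 fps), renders
the joint centres to 3-D markers at 30 fps in the x–y plane, prepends a
5 s static window, and adds seeded isotropic Gaussian noise (default
σ = 5 mm, typical depth-camera jitter) to all markers.  The cohort sampler
draws per-subject weights from log-normal clouds centred on the two group
presets (σ = 0.10 log₁₀ units ≈ ×/÷1.26 per weight — large within-group
spread, yet the 0.28-decade separation of the group *ratios* keeps the
two-group contrast clearly resolvable at 13 vs 19 subjects), and varies
height (1.50–1.83 m) and body mass (56–90 kg) over the reported ranges,
with segment lengths as standard fractions of height.

What the synthetic benchmark shows: that the full blind pipeline —
rendering, noise, resampling, scaling, onset detection, fitting, group
statistics — recovers the generating parameters and group structure.
What it does not show: robustness to marker dropout and occlusion,
out-of-plane shoulder motion, soft-tissue artefact, tremor or other
structured (non-Gaussian, non-stationary) noise, or mis-specified
anthropometry; real recordings violate the planar rigid-body model in
ways no parameter of this generator emulates.

## Numerical choices and degenerate inputs

* ARE residual tolerance 1e-8·(1+‖S‖); non-stabilizable pairs are
  diagnosed with a PBH test naming the uncoupled mode.
* Modal propagation falls back to repeated `expm` when the closed-loop
  eigenbasis is badly conditioned; fully decayed stiff modes underflow
  cleanly.
* Onset detection anchors on a *sustained* large excursion (≥6 of 8
  samples above max(5·threshold, 0.1 m)) before walking back to the last
  quiet sample, so correlated noise blips and the alternating-sign
  spectral edge ringing of a finite record cannot trigger a false onset;
  the low threshold defaults to 2 cm.
* The trajectory-matching window trims 0.25 s from the record's end to
  keep the strongest edge ringing out of the error.
* Degenerate geometry (non-positive masses/lengths, centre of mass beyond
  the segment) and malformed recordings (missing joints, unparseable
  rows, non-uniform frame times) are rejected with specific messages.
* Simulation sizes in the tests and the acceptance script (10 s motions,
  20–60 s analysis records, 13+19-subject cohorts, 50-gain optimality
  checks) were chosen as the smallest sizes at which each property is
  cleanly measurable on a single core.

## Known limitations

* Planar kinematics only; no abduction or axial rotation.
* No muscle model, joint friction or damping; torques act directly at the
  joints, and the fitted torque scale is set by the dimensionless cost
  weights rather than physiological limits.
* The weight magnitude is unidentifiable at realistic noise (see above);
  only the ratio should be interpreted from field data.
* Group comparisons run two separate Welch tests (θ_p, ω_p) without
  multiple-testing correction, mirroring two planned comparisons; in
  pinned-magnitude mode the two tests are not independent (both are
  driven by the ratio).
* The Fourier resampler assumes an essentially uniform frame clock;
  dropped frames are linearly interpolated first, which low-passes short
  gaps.
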