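# armoc — inverse optimal control of arm flexion

`armoc` quantifies the neuromotor control of a shoulder-flexion movement
(raising the arm against gravity) by estimating the cost functional an
optimal controller would have to minimize to reproduce a measured wrist
trajectory.  It is aimed at motor-control researchers and clinician
scientists who record reaching movements with a depth camera or marker
system and want a compact, physiologically interpretable descriptor of how
a subject penalizes posture error versus movement speed.

## The model

The arm is a frictionless planar chain of three rigid links (upper arm,
forearm, hand) with revolute joints at the shoulder, elbow and wrist,
gravity acting at each segment's centre of mass, and a smooth sigmoid
torque keeping each joint inside its physiological range.  With state
x = [θ₁, θ₂, θ₃, ω₁, ω₂, ω₃]ᵀ and joint torques c, the equations of motion
M(x) dx/dt = r(x, c) are linearized about the raised target posture — a
gravitationally unstable equilibrium — giving dx/dt = A x + B c.

The neural controller is modelled as the linear quadratic regulator
minimizing

    J = ∫₀^∞ ( xᵀ Z x + cᵀ U c ) dt,
    Z = diag(θ_p, θ_p, θ_p, ω_p, ω_p, ω_p),   U = I₃,

whose optimal feedback c = −K x follows from the stabilizing solution S of
the continuous algebraic Riccati equation −SA − AᵀS + SBU⁻¹BᵀS − Z = 0,
with K = U⁻¹BᵀS.  The two scalars are the scientific output: **θ_p**
penalizes squared joint-angle deviation (inability to hold intermediate
postures when it is high relative to motion cost), **ω_p** penalizes
squared joint velocity (low values produce fast, jerky movements).

The *inverse* problem personalizes (θ_p, ω_p): Nelder–Mead search in
log₁₀-space where each candidate is pushed through the full forward
pipeline — build Z, solve the Riccati equation, simulate the closed-loop
flexion from the measured start posture, render the wrist height through
the same 30 fps sampling and Fourier-resampling steps as the data — and is
scored by the ℓ₂ error of the wrist's vertical displacement.  The movement
onset is co-estimated as a nuisance parameter, and the overall magnitude
√(θ_p ω_p) is refined on the nonlinear plant (or pinned to a reference
scale for noisy cohort data; see `docs/methods.md`).

Two downstream analyses characterize the fitted controller:

* **Velocity resistance** — partitioning K = [K₁ | K₂] into angle and
  velocity feedback blocks, the direction x₂\* maximizing ‖K₂x₂‖ (leading
  right singular vector) is the joint-velocity direction the controller
  resists most, with magnitude τ\*.
* **Perturbation response** — feedback is driven with a perturbed state
  x + κ·cos(γt)·**1**; the resulting wrist signal is analysed with a
  pseudo-Wigner–Ville distribution W(t, f) and its cumulative energy
  E(t,f) = ∫∫ W, swept over perturbation frequencies γ and normalized by
  the maximum response.

Because no public recording of this protocol exists, the package ships a
first-class synthetic-data generator: LQR-driven flexion of the nonlinear
plant rendered to 30 fps 3-D markers with a 5 s static window and seeded
Gaussian marker noise, plus a two-group cohort sampler with per-subject
anthropometry.

## Worked example

Generate a noiseless synthetic recording at the patient-group cost
functional, ingest it as if it were real data, and fit the weights blind:

```python
import numpy as np
from armoc import (PRESET_PATIENT, SyntheticSpec, fit_weights,
                   generate_recording, stiffness_report, lqr_gain,
                   linearize, derive_eom, ArmGeometry)
from armoc.kinect_io import ingest_recording

spec = SyntheticSpec(weights=PRESET_PATIENT, noise_sigma=0.0, seed=7)
recording, truth = generate_recording(spec)
measured = ingest_recording(recording)

fit = fit_weights(measured)
w = fit.weights
print(f"theta_p = {w.theta_p:,.0f}   omega_p = {w.omega_p:,.0f}")
print(f"ratio theta_p/omega_p = {w.ratio:.3f}   "
      f"matching error = {fit.error:.2e}   onset = {fit.onset_s:.3f} s")

geometry = ArmGeometry.from_anthropometry(70.0, fit.lengths)
linsys = linearize(derive_eom(geometry), fit.x_star)
K, _ = lqr_gain(linsys, w)
rep = stiffness_report(K)
print(f"tau* = {rep.tau_star:.1f} N m   x2* = {np.round(rep.x2_star, 4)}")
```

Output:

```
theta_p = 13,967,425   omega_p = 5,251,507
ratio theta_p/omega_p = 2.660   matching error = 3.91e-07   onset = 5.000 s
tau* = 2292.3 N m   x2* = [0.9445 0.3274 0.0262]
```

The generating weights were (13,950,617, 5,245,197): both are recovered to
about 0.1 %, the movement onset (5 s of static window precede the motion)
to a millisecond, and the wrist trajectories match to sub-micron ℓ₂ error.
τ\* says the controller opposes a unit joint-velocity excursion along x₂\*
(dominantly the shoulder) with ≈2292 N m of torque; the healthy preset
yields ≈3053 N m along the same direction — patients resist unwanted
velocity less.

## Command-line workflow

```bash
armoc synth  --cohort 13 19 --seed 7 --outdir data/       # synthetic cohort
armoc ingest --in data/n000.csv --out scaled.json         # resample + scale
armoc fit    --recording data/n000.csv --out fit.json     # estimate weights
armoc stiffness --fit fit.json --out stiffness.json       # tau*, x2*
armoc perturb --fit fit.json --freqs 0.5:45.5:1.0 --out sweep.csv
armoc compare --fits fits/ --labels labels.csv --out report.json
```

Recordings are long-format CSV (`time_s,joint,x_m,y_m,z_m`, one row per
joint per frame) with markers named `shoulder`, `elbow`, `wrist`, `hand`.

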