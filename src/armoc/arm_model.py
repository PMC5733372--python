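"""Planar three-link arm: rigid-body dynamics, kinematics, and linearisation.

The arm is modelled as a frictionless serial chain of three rigid links
(upper arm, forearm, hand) rotating about revolute joints (shoulder, elbow,
wrist) in a vertical plane, with the shoulder fixed at the origin of an
inertial frame and gravity acting at each segment's centre of mass.

Angle convention
----------------
``theta_1`` is the shoulder angle measured from the *downward* vertical
(hanging rest posture = 0); ``theta_2`` and ``theta_3`` are the elbow and
wrist angles measured relative to the proximal segment.  Flexion (raising
the arm forward/upward) is positive.  The state vector is
``x = [theta_1, theta_2, theta_3, omega_1, omega_2, omega_3]`` with angles
in radians and angular velocities in rad/s, stored unwrapped.

A smooth (C-infinity) sigmoid joint-limit torque keeps each joint inside a
physiological range in the nonlinear plant; it is a restoring torque that is
negligible strictly inside the range and rises steeply at the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "ArmGeometry",
    "JointLimits",
    "NonlinearDynamics",
    "LinearizedSystem",
    "Trajectory",
    "derive_eom",
    "joint_limit_torque",
    "forward_kinematics",
    "linearize",
    "simulate",
]

# Lower-triangular map from relative joint angles to absolute link angles:
# phi = L @ theta, with phi_i the angle of link i from the downward vertical.
_L = np.tril(np.ones((3, 3)))

# Anthropometric segment fractions (Winter's tables): segment mass as a
# fraction of body mass, and centre-of-mass location as a fraction of
# segment length from the proximal joint, for upper arm / forearm / hand.
_MASS_FRACTION = (0.028, 0.016, 0.006)
_COM_FRACTION = (0.436, 0.430, 0.506)

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths, masses, centre-of-mass offsets and inertias.

    Parameters
    ----------
    lengths : tuple of float
        Segment lengths ``(l1, l2, l3)`` in metres (upper arm, forearm, hand).
    masses : tuple of float
        Segment masses in kg.
    com : tuple of float
        Centre-of-mass distance from the proximal joint of each segment (m).
    inertias : tuple of float
        Moments of inertia about each segment's centre of mass (kg m^2).
    g : float
        Gravitational acceleration (m/s^2).
    """

    lengths: tuple[float, float, float] = (0.30, 0.26, 0.08)
    masses: tuple[float, float, float] = (1.96, 1.12, 0.42)
    com: tuple[float, float, float] = (0.1308, 0.1118, 0.04048)
    inertias: tuple[float, float, float] = (0.0147, 0.006311, 0.000224)
    g: float = 9.81

    def __post_init__(self) -> None:
        l, m, c, i = (np.asarray(v, float) for v in
                      (self.lengths, self.masses, self.com, self.inertias))
        if l.shape != (3,) or m.shape != (3,) or c.shape != (3,) or i.shape != (3,):
            raise ValueError("geometry requires three segments")
        if not (np.all(l > 0) and np.all(m > 0) and np.all(i > 0)):
            raise ValueError(
                "degenerate geometry: lengths, masses and inertias must be "
                f"strictly positive (got l={self.lengths}, m={self.masses}, "
                f"I={self.inertias})")
        if not (np.all(c > 0) and np.all(c <= l)):
            raise ValueError("centre-of-mass offsets must satisfy 0 < c_i <= l_i")
        if self.g < 0:
            raise ValueError("g must be non-negative")

    @classmethod
    def from_anthropometry(
        cls,
        body_mass: float = 70.0,
        lengths: tuple[float, float, float] = (0.30, 0.26, 0.08),
        g: float = 9.81,
    ) -> "ArmGeometry":
        """Build a geometry from body mass and measured segment lengths.

        Segment masses are standard fractions of body mass (2.8 % upper arm,
        1.6 % forearm, 0.6 % hand), the centre of mass sits at the usual
        fraction of segment length from the proximal joint, and each segment
        is treated as a uniform rod for its moment of inertia.
        """
        if body_mass <= 0:
            raise ValueError("body mass must be positive")
        l = np.asarray(lengths, float)
        m = body_mass * np.asarray(_MASS_FRACTION)
        c = l * np.asarray(_COM_FRACTION)
        inertia = m * l ** 2 / 12.0  # uniform rod about its COM
        return cls(tuple(l), tuple(m), tuple(c), tuple(inertia), g)


@dataclass(frozen=True)
class JointLimits:
    """Sigmoid joint-range constraint (shoulder, elbow, wrist).

    The restoring torque on joint ``i`` is

        tau_i = scale * (sigma(-s (theta_i - lower_i)) - sigma(s (theta_i - upper_i)))

    with ``sigma`` the logistic function and ``s`` the steepness (1/rad).
    The torque is infinitely differentiable, essentially zero strictly inside
    the range, and opposes excursion beyond either bound.
    """

    lower: tuple[float, float, float] = (-60 * _DEG, 0.0, -70 * _DEG)
    upper: tuple[float, float, float] = (200 * _DEG, 150 * _DEG, 80 * _DEG)
    steepness: float = 30.0
    scale: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("limits require three joints")
        if not np.all(lo < hi):
            raise ValueError("each lower bound must be below the upper bound")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.scale < 0:
            raise ValueError("torque scale must be non-negative")

    def torque(self, theta: np.ndarray) -> np.ndarray:
        """Constraint torque (N m) at joint angles ``theta`` (rad)."""
        theta = np.asarray(theta, float)
        s = self.steepness
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return self.scale * (expit(-s * (theta - lo)) - expit(s * (theta - hi)))

    def torque_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Diagonal of d(tau)/d(theta) at ``theta`` (N m / rad)."""
        theta = np.asarray(theta, float)
        s = self.steepness
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        p_lo = expit(-s * (theta - lo))
        p_hi = expit(s * (theta - hi))
        return -self.scale * s * (p_lo * (1 - p_lo) + p_hi * (1 - p_hi))

    @classmethod
    def disabled(cls) -> "JointLimits":
        """Limits with zero torque scale (constraint switched off)."""
        return cls(scale=0.0)


def joint_limit_torque(state: np.ndarray, limits: JointLimits) -> np.ndarray:
    """Constraint torque for a full state vector (uses the angle block)."""
    x = np.asarray(state, float)
    return limits.torque(x[..., :3])


class NonlinearDynamics:
    """Equations of motion of the three-link arm, ``M(x) dx/dt = r(x, c)``.

    Internally the dynamics are written in absolute link angles
    ``phi = L theta`` where the mass matrix has the classic n-link pendulum
    form ``M_jk = I_j delta_jk + beta_jk cos(phi_j - phi_k)`` and the forcing
    collects centrifugal/Coriolis and gravity terms; they are mapped back to
    relative joint coordinates with the constant matrix ``L``.
    """

    def __init__(self, geometry: ArmGeometry, limits: JointLimits | None = None):
        self.geometry = geometry
        self.limits = limits if limits is not None else JointLimits()
        l = np.asarray(geometry.lengths)
        m = np.asarray(geometry.masses)
        c = np.asarray(geometry.com)
        # a[i, j]: lever arm of absolute angle j in the COM position of link i
        a = np.zeros((3, 3))
        for i in range(3):
            a[i, :i] = l[:i]
            a[i, i] = c[i]
        self._beta = a.T @ np.diag(m) @ a          # coupling inertia terms
        self._w = m @ a                             # gravity lever weights
        self._I = np.asarray(geometry.inertias)

    # -- building blocks in absolute coordinates ---------------------------

    def _mass_matrix_abs(self, phi: np.ndarray) -> np.ndarray:
        dphi = phi[:, None] - phi[None, :]
        return np.diag(self._I) + self._beta * np.cos(dphi)

    def _bias_abs(self, phi: np.ndarray, phid: np.ndarray) -> np.ndarray:
        """Centrifugal + gravity generalized forces (sign: appears as -bias)."""
        dphi = phi[:, None] - phi[None, :]
        centrifugal = (self._beta * np.sin(dphi)) @ (phid ** 2)
        gravity = self.geometry.g * self._w * np.sin(phi)
        return centrifugal + gravity

    # -- public surface in relative joint coordinates ----------------------

    def mass_matrix(self, x: np.ndarray) -> np.ndarray:
        """Full 6x6 matrix of ``M(x) dx/dt = r(x, c)`` (kinematic block = I)."""
        x = np.asarray(x, float)
        phi = _L @ x[:3]
        M = np.eye(6)
        M[3:, 3:] = _L.T @ self._mass_matrix_abs(phi) @ _L
        return M

    def forcing(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Right-hand side vector ``r(x, c)`` of ``M dx/dt = r``."""
        x = np.asarray(x, float)
        c = np.asarray(c, float)
        theta, omega = x[:3], x[3:]
        phi, phid = _L @ theta, _L @ omega
        torque = c + self.limits.torque(theta)
        r = np.empty(6)
        r[:3] = omega
        r[3:] = torque - _L.T @ self._bias_abs(phi, phid)
        return r

    def derivative(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        """State derivative ``f(x, c) = M(x)^{-1} r(x, c)``."""
        x = np.asarray(x, float)
        c = np.asarray(c, float)
        theta, omega = x[:3], x[3:]
        phi, phid = _L @ theta, _L @ omega
        M_rel = _L.T @ self._mass_matrix_abs(phi) @ _L
        rhs = c + self.limits.torque(theta) - _L.T @ self._bias_abs(phi, phid)
        out = np.empty(6)
        out[:3] = omega
        out[3:] = np.linalg.solve(M_rel, rhs)
        return out

    def total_energy(self, x: np.ndarray) -> float:
        """Kinetic plus gravitational potential energy (J).

        The potential is measured from the configuration in which every
        link angle is 90 degrees (all links horizontal).
        """
        x = np.asarray(x, float)
        phi, phid = _L @ x[:3], _L @ x[3:]
        kinetic = 0.5 * phid @ self._mass_matrix_abs(phi) @ phid
        potential = -self.geometry.g * self._w @ np.cos(phi)
        return float(kinetic + potential)

    def equilibrium_torque(self, theta: np.ndarray) -> np.ndarray:
        """Joint torque holding the arm still at posture ``theta``.

        Compensates gravity and the (usually negligible) joint-limit torque
        so that the posture with zero velocity is an exact equilibrium.
        """
        theta = np.asarray(theta, float)
        phi = _L @ theta
        gravity = self.geometry.g * self._w * np.sin(phi)
        return _L.T @ gravity - self.limits.torque(theta)


def derive_eom(geometry: ArmGeometry, limits: JointLimits | None = None) -> NonlinearDynamics:
    """Assemble the arm's equations of motion (closed-form rigid-body chain)."""
    return NonlinearDynamics(geometry, limits)


def forward_kinematics(state: np.ndarray, geometry: ArmGeometry) -> dict[str, np.ndarray]:
    """Planar positions of the elbow, wrist and hand tip (shoulder at origin).

    Accepts a single state/angle vector or an array whose last axis holds at
    least the three joint angles; returns arrays with a trailing (x, y) axis,
    where x is the horizontal flexion direction and y points upward.
    """
    arr = np.asarray(state, float)
    theta = arr[..., :3]
    phi = theta @ _L.T
    l = np.asarray(geometry.lengths)
    seg = np.stack([np.sin(phi), -np.cos(phi)], axis=-1) * l[:, None]
    elbow = seg[..., 0, :]
    wrist = elbow + seg[..., 1, :]
    hand = wrist + seg[..., 2, :]
    shoulder = np.zeros_like(elbow)
    return {"shoulder": shoulder, "elbow": elbow, "wrist": wrist, "hand": hand}


@dataclass(frozen=True)
class LinearizedSystem:
    """First-order linear model ``d(dx)/dt = A dx + B dc`` about ``(x*, c*)``."""

    A: np.ndarray
    B: np.ndarray
    x_star: np.ndarray
    c_star: np.ndarray

    def __post_init__(self) -> None:
        if self.A.shape != (6, 6) or self.B.shape != (6, 3):
            raise ValueError("A must be 6x6 and B 6x3")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("linearized system contains non-finite entries")


def linearize(dyn: NonlinearDynamics, x_star: np.ndarray) -> LinearizedSystem:
    """Linearize the arm about a zero-velocity posture ``x_star``.

    The Jacobians are evaluated analytically: at the gravity-compensated
    equilibrium the forcing vanishes, so the derivative of ``M^{-1} r``
    reduces to ``M^{-1}`` times the gradients of the gravity and joint-limit
    torques; there is no velocity feedback in a frictionless chain.
    """
    x_star = np.asarray(x_star, float)
    if x_star.shape != (6,):
        raise ValueError("x_star must be a 6-vector")
    if np.any(np.abs(x_star[3:]) > 1e-12):
        raise ValueError("linearization point must have zero velocities")
    theta = x_star[:3]
    phi = _L @ theta
    M_rel = _L.T @ dyn._mass_matrix_abs(phi) @ _L
    cond = np.linalg.cond(M_rel)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("mass matrix is singular at x_star")
    grav_grad = _L.T @ np.diag(dyn.geometry.g * dyn._w * np.cos(phi)) @ _L
    lim_grad = np.diag(dyn.limits.torque_jacobian(theta))
    Minv = np.linalg.inv(M_rel)
    A = np.zeros((6, 6))
    A[:3, 3:] = np.eye(3)
    A[3:, :3] = Minv @ (lim_grad - grav_grad)
    B = np.zeros((6, 3))
    B[3:, :] = Minv
    c_star = dyn.equilibrium_torque(theta)
    return LinearizedSystem(A=A, B=B, x_star=x_star, c_star=c_star)


@dataclass
class Trajectory:
    """A simulated or reconstructed motion on a uniform time grid.

    Attributes
    ----------
    t : ndarray, shape (N,)
        Time stamps (s), strictly increasing and uniform.
    x : ndarray, shape (N, 6)
        State samples.
    torque : ndarray, shape (N, 3)
        Applied joint torques at each sample (N m).
    geometry : ArmGeometry
        Geometry used to derive Cartesian quantities.
    """

    t: np.ndarray
    x: np.ndarray
    torque: np.ndarray
    geometry: ArmGeometry

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.torque = np.asarray(self.torque, float)
        n = self.t.size
        if self.x.shape != (n, 6) or self.torque.shape != (n, 3):
            raise ValueError("state and torque must have one row per sample")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def fps(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def positions(self) -> dict[str, np.ndarray]:
        return forward_kinematics(self.x, self.geometry)

    def wrist_xy(self) -> np.ndarray:
        return self.positions()["wrist"]

    def elbow_xy(self) -> np.ndarray:
        return self.positions()["elbow"]

    def wrist_velocity_xy(self) -> np.ndarray:
        """Exact wrist velocity from the chain Jacobian (no numerical diff)."""
        phi = self.x[:, :3] @ _L.T
        phid = self.x[:, 3:] @ _L.T
        l = np.asarray(self.geometry.lengths)
        dseg = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
        v = (dseg[:, :2, :] * (l[:2] * phid[:, :2])[:, :, None]).sum(axis=1)
        return v

    def wrist_speed(self) -> np.ndarray:
        return np.linalg.norm(self.wrist_velocity_xy(), axis=1)


def simulate(
    dyn: NonlinearDynamics,
    controller: Callable[[float, np.ndarray], np.ndarray],
    x0: np.ndarray,
    t_final: float,
    dt: float = 1.0 / 60.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the closed- or open-loop arm and sample on a uniform grid.

    ``controller(t, x)`` returns the 3-vector of joint torques; the stiff
    variable-step integrator keeps local error below the given tolerances
    and the solution is reported every ``dt`` seconds.
    """
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    x0 = np.asarray(x0, float)
    n = int(round(t_final / dt)) + 1
    t_eval = np.arange(n) * dt

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        return dyn.derivative(x, controller(t, x))

    sol = solve_ivp(rhs, (0.0, t_eval[-1]), x0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.4f} s: "
            f"{sol.message}")
    x = sol.y.T
    torque = np.array([controller(t, xi) for t, xi in zip(sol.t, x)])
    return Trajectory(t=sol.t, x=x, torque=torque, geometry=dyn.geometry)
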