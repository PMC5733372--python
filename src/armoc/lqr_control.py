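"""Infinite-horizon LQR design for the linearized arm.

The controller minimizes

    J = int_0^inf ( x' Z x + c' U c ) dt

subject to ``dx/dt = A x + B c``, with the state penalty restricted to the
diagonal family ``Z = diag(theta_p, theta_p, theta_p, omega_p, omega_p,
omega_p)`` and the control penalty fixed to ``U = I``.  The stabilizing
solution ``S`` of the continuous algebraic Riccati equation

    -S A - A' S + S B U^{-1} B' S - Z = 0

yields the feedback gain ``K = U^{-1} B' S`` and the optimal control
``c = -K x`` (applied about the target equilibrium).

Only the ratio theta_p : omega_p : 1 (the implicit unit weight on the
torques) shapes the gain; scaling Z and U together leaves K unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig, expm, solve_continuous_are

from .arm_model import LinearizedSystem, NonlinearDynamics, Trajectory, simulate

__all__ = [
    "CostWeights",
    "RiccatiSolution",
    "GainMatrix",
    "U_IDENTITY",
    "PRESET_NORMAL",
    "PRESET_PATIENT",
    "build_Z",
    "solve_riccati",
    "gain",
    "lqr_gain",
    "feedback_controller",
    "propagate_linear",
    "linear_closed_loop_trajectory",
    "simulated_cost",
    "evaluate_cost",
]

U_IDENTITY = np.eye(3)


@dataclass(frozen=True)
class CostWeights:
    """Penalties on squared joint angles (theta_p) and velocities (omega_p)."""

    theta_p: float
    omega_p: float

    def __post_init__(self) -> None:
        if not (self.theta_p > 0 and self.omega_p > 0):
            raise ValueError(
                "cost weights must be strictly positive so that Z is "
                f"positive definite (got theta_p={self.theta_p}, "
                f"omega_p={self.omega_p})")

    @property
    def ratio(self) -> float:
        """theta_p / omega_p, the shape parameter of the cost contours."""
        return self.theta_p / self.omega_p


# Group-representative cost functionals reported for healthy controls and
# for patients with mild neuromotor abnormalities.
PRESET_NORMAL = CostWeights(theta_p=12_926_292.0, omega_p=9_315_830.0)
PRESET_PATIENT = CostWeights(theta_p=13_950_617.0, omega_p=5_245_197.0)


@dataclass(frozen=True)
class RiccatiSolution:
    """Stabilizing solution of the continuous ARE, with its defining data."""

    S: np.ndarray
    A: np.ndarray
    B: np.ndarray
    Z: np.ndarray
    U: np.ndarray
    residual: float


@dataclass(frozen=True)
class GainMatrix:
    """State-feedback gain ``K`` (3x6) with angle/velocity partition."""

    K: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.K).shape != (3, 6):
            raise ValueError("gain must be 3x6")

    @property
    def K1(self) -> np.ndarray:
        return self.K[:, :3]

    @property
    def K2(self) -> np.ndarray:
        return self.K[:, 3:]


def build_Z(weights: CostWeights) -> np.ndarray:
    """Diagonal state penalty diag(theta_p x3, omega_p x3)."""
    return np.diag([weights.theta_p] * 3 + [weights.omega_p] * 3)


def _pbh_diagnostic(A: np.ndarray, B: np.ndarray) -> str:
    """Name the least controllable mode via the PBH rank test."""
    vals, vecs = eig(A.T)
    worst = None
    for lam, v in zip(vals, vecs.T):
        coupling = np.linalg.norm(B.T @ v)
        if worst is None or coupling < worst[1]:
            worst = (lam, coupling)
    lam, coupling = worst
    return (f"mode with eigenvalue {lam:.6g} couples to the input with "
            f"norm {coupling:.3g}")


def solve_riccati(A: np.ndarray, B: np.ndarray, Z: np.ndarray,
                  U: np.ndarray) -> RiccatiSolution:
    """Stabilizing symmetric solution of the continuous ARE.

    Uses a Schur/invariant-subspace solver; the residual of the equation is
    verified to be below ``1e-8 * (1 + ||S||_F)``.
    """
    A, B, Z, U = (np.asarray(m, float) for m in (A, B, Z, U))
    try:
        S = solve_continuous_are(A, B, Z, U)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "Riccati solve failed; the pair (A, B) may not be stabilizable: "
            + _pbh_diagnostic(A, B)) from err
    S = 0.5 * (S + S.T)
    Uinv = np.linalg.inv(U)
    res = np.linalg.norm(-S @ A - A.T @ S + S @ B @ Uinv @ B.T @ S - Z)
    bound = 1e-8 * (1.0 + np.linalg.norm(S))
    if res > bound:
        raise np.linalg.LinAlgError(
            f"ARE residual {res:.3g} exceeds tolerance {bound:.3g}")
    return RiccatiSolution(S=S, A=A, B=B, Z=Z, U=U, residual=float(res))


def gain(S: RiccatiSolution | np.ndarray, B: np.ndarray | None = None,
         U: np.ndarray | None = None, A: np.ndarray | None = None) -> GainMatrix:
    """Feedback gain ``K = U^{-1} B' S``; closed-loop stability is asserted.

    Accepts either a :class:`RiccatiSolution` (B, U, A taken from it) or a
    raw ``S`` matrix with ``B`` and ``U`` given explicitly.
    """
    if isinstance(S, RiccatiSolution):
        A = S.A if A is None else A
        B, U, S = S.B, S.U, S.S
    if B is None or U is None:
        raise ValueError("B and U are required when S is a bare matrix")
    K = np.linalg.solve(np.asarray(U, float), np.asarray(B, float).T @ S)
    if A is not None:
        poles = np.linalg.eigvals(np.asarray(A, float) - B @ K)
        if np.max(poles.real) >= 0:
            raise np.linalg.LinAlgError(
                "closed loop is not stable (wrong Riccati branch?): "
                f"max Re(eig) = {np.max(poles.real):.3g}")
    if K.shape == (3, 6):
        return GainMatrix(K=K)
    return K  # small benchmark problems keep their natural shape


def lqr_gain(linsys: LinearizedSystem,
             weights: CostWeights,
             U: np.ndarray | None = None) -> tuple[GainMatrix, RiccatiSolution]:
    """Design the LQR gain for the linearized arm at the given weights."""
    U = U_IDENTITY if U is None else U
    sol = solve_riccati(linsys.A, linsys.B, build_Z(weights), U)
    return gain(sol), sol


def feedback_controller(linsys: LinearizedSystem, K: GainMatrix):
    """Torque law ``c(t, x) = c* - K (x - x*)`` for use with ``simulate``."""
    Km, x_star, c_star = K.K, linsys.x_star, linsys.c_star

    def controller(t: float, x: np.ndarray) -> np.ndarray:
        return c_star - Km @ (x - x_star)

    return controller


def _modal(Acl: np.ndarray):
    lam, V = np.linalg.eig(Acl)
    if np.linalg.cond(V) > 1e10:
        raise np.linalg.LinAlgError("closed-loop matrix is too close to defective")
    return lam, V


def propagate_linear(Acl: np.ndarray, d0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sample ``exp(Acl t) d0`` on a time grid via the eigen-decomposition.

    Falls back to repeated matrix exponentials if the eigenbasis is badly
    conditioned.  Handles arbitrarily stiff modes: fully decayed exponentials
    underflow cleanly to zero.
    """
    t = np.asarray(t, float)
    try:
        lam, V = _modal(Acl)
    except np.linalg.LinAlgError:
        step = expm(Acl * (t[1] - t[0]))
        out = np.empty((t.size, d0.size))
        cur = d0.astype(float)
        for i in range(t.size):
            out[i] = cur
            cur = step @ cur
        return out
    y0 = np.linalg.solve(V, d0.astype(complex))
    z = lam[None, :] * t[:, None]
    z = np.clip(z.real, -745.0, 50.0) + 1j * z.imag
    return np.real(np.exp(z) * y0[None, :] @ V.T)


def linear_closed_loop_trajectory(
    linsys: LinearizedSystem,
    K: GainMatrix,
    x0: np.ndarray,
    t_final: float,
    fps: float = 60.0,
    geometry=None,
) -> Trajectory:
    """Exact closed-loop solution of the linear plant, sampled at ``fps``.

    The linear flow is evaluated through the eigen-decomposition of
    ``A - B K``, which remains accurate for the very stiff loops produced by
    large cost weights (where fixed-step integration would be hopeless).
    """
    Acl = linsys.A - linsys.B @ K.K
    n = int(round(t_final * fps)) + 1
    t = np.arange(n) / fps
    d0 = np.asarray(x0, float) - linsys.x_star
    dev = propagate_linear(Acl, d0, t)
    x = linsys.x_star[None, :] + dev
    torque = linsys.c_star[None, :] - dev @ K.K.T
    return Trajectory(t=t, x=x, torque=torque, geometry=geometry)


def simulated_cost(A: np.ndarray, B: np.ndarray, K: np.ndarray,
                   Z: np.ndarray, U: np.ndarray, x0: np.ndarray,
                   t_final: float = 30.0, rtol: float = 1e-10,
                   atol: float = 1e-12) -> float:
    """Closed-loop quadratic cost from ``x0`` by adaptive integration.

    Augments the closed-loop ODE with the running cost
    ``x'(Z + K'UK)x`` and integrates both with a stiff-capable solver, so
    the result is a genuine simulation rather than a Lyapunov identity.
    """
    from scipy.integrate import solve_ivp

    K = K.K if isinstance(K, GainMatrix) else np.asarray(K, float)
    Acl = A - B @ K
    Q = Z + K.T @ U @ K

    def rhs(t, y):
        x = y[:-1]
        return np.concatenate([Acl @ x, [x @ Q @ x]])

    y0 = np.concatenate([np.asarray(x0, float), [0.0]])
    sol = solve_ivp(rhs, (0.0, t_final), y0, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cost integration failed: {sol.message}")
    return float(sol.y[-1, -1])


@dataclass(frozen=True)
class CostBreakdown:
    """Quadrature of the LQR cost along a trajectory."""

    J: float
    I_v: np.ndarray       # state-penalty integrand series
    I_c: np.ndarray       # control-penalty integrand series
    Omega: np.ndarray     # sqrt(omega_1^2 + omega_2^2 + omega_3^2)
    Theta: np.ndarray     # sqrt(theta_1^2 + theta_2^2 + theta_3^2)


def evaluate_cost(traj: Trajectory, weights: CostWeights,
                  x_star: np.ndarray | None = None,
                  c_star: np.ndarray | None = None,
                  U: np.ndarray | None = None) -> CostBreakdown:
    """Trapezoidal quadrature of ``x'Zx + c'Uc`` along a sampled trajectory.

    States (and torques) are expressed as deviations from the target
    equilibrium before squaring; ``I_v = omega_p Omega^2 + theta_p Theta^2``
    where Omega and Theta collect the angular-velocity and angle deviations.
    """
    U = U_IDENTITY if U is None else U
    dx = traj.x - (0 if x_star is None else np.asarray(x_star, float))
    dc = traj.torque - (0 if c_star is None else np.asarray(c_star, float))
    Theta2 = (dx[:, :3] ** 2).sum(axis=1)
    Omega2 = (dx[:, 3:] ** 2).sum(axis=1)
    I_v = weights.theta_p * Theta2 + weights.omega_p * Omega2
    I_c = np.einsum("ni,ij,nj->n", dc, U, dc)
    J = float(np.trapezoid(I_v + I_c, traj.t))
    return CostBreakdown(J=J, I_v=I_v, I_c=I_c,
                         Omega=np.sqrt(Omega2), Theta=np.sqrt(Theta2))
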