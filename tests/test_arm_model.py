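"""Rigid-body dynamics, kinematics and linearization of the three-link arm."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from armoc import (ArmGeometry, JointLimits, Trajectory, derive_eom,
                   forward_kinematics, joint_limit_torque, linearize,
                   simulate)
from armoc.arm_model import _L

from conftest import ARM_UP


# ---------------------------------------------------------------- geometry

@pytest.mark.parametrize("field,value", [
    ("lengths", (0.0, 0.26, 0.08)),
    ("masses", (1.96, -1.0, 0.42)),
    ("com", (0.4, 0.11, 0.04)),       # com beyond segment length
    ("inertias", (0.0147, 0.0, 0.0002)),
])
def test_degenerate_geometry_rejected(field, value):
    kwargs = {field: value}
    with pytest.raises(ValueError):
        ArmGeometry(**kwargs)


def test_anthropometric_geometry_matches_defaults():
    geo = ArmGeometry.from_anthropometry(body_mass=70.0)
    ref = ArmGeometry()
    assert np.allclose(geo.masses, ref.masses)
    assert np.allclose(geo.com, ref.com, atol=1e-12)
    assert np.allclose(geo.inertias, ref.inertias, atol=1e-4)


# ----------------------------------------------------------- joint limits

def test_limit_torque_negligible_at_midrange(limits):
    mid = 0.5 * (np.asarray(limits.lower) + np.asarray(limits.upper))
    tau = limits.torque(mid)
    assert np.all(np.abs(tau) < 1e-3 * limits.scale)


def test_limit_torque_matches_sigmoid_formula(limits):
    from scipy.special import expit
    theta = np.asarray(limits.upper) + 0.05
    tau = limits.torque(theta)
    s = limits.steepness
    expected = limits.scale * (expit(-s * (theta - np.asarray(limits.lower)))
                               - expit(s * (theta - np.asarray(limits.upper))))
    assert np.allclose(tau, expected, rtol=0, atol=1e-15)
    assert np.all(tau < 0)            # restoring: pushes back below the bound


def test_limit_torque_disabled_by_zero_scale():
    lim = JointLimits.disabled()
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(0, 2, 6)
        assert np.all(joint_limit_torque(x, lim) == 0.0)


@given(st.floats(-3.0, 3.0), st.floats(-3.0, 3.0))
@settings(max_examples=30, deadline=None)
def test_limit_torque_monotone_in_angle(a, b):
    """The restoring torque never increases when the angle increases."""
    lim = JointLimits()
    lo, hi = min(a, b), max(a, b)
    t_lo = lim.torque(np.array([lo, lo, lo]))
    t_hi = lim.torque(np.array([hi, hi, hi]))
    assert np.all(t_hi <= t_lo + 1e-12)


# ------------------------------------------------------ forward kinematics

def test_hanging_rest_chain_points_straight_down(geometry):
    pos = forward_kinematics(np.zeros(6), geometry)
    l1, l2, l3 = geometry.lengths
    assert np.allclose(pos["wrist"], [0.0, -(l1 + l2)], atol=1e-14)
    assert np.allclose(pos["hand"], [0.0, -(l1 + l2 + l3)], atol=1e-14)


def test_ninety_degree_flexion_is_horizontal(geometry):
    x = np.array([np.pi / 2, 0, 0, 0, 0, 0.0])
    pos = forward_kinematics(x, geometry)
    l1, l2 = geometry.lengths[:2]
    assert np.allclose(pos["wrist"], [l1 + l2, 0.0], atol=1e-14)


def test_positions_match_rotation_composition_oracle(geometry):
    """Brute-force chain of 2-D rotation matrices as an independent oracle."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        theta = rng.uniform(-np.pi, np.pi, 3)
        x = np.concatenate([theta, np.zeros(3)])
        pos = forward_kinematics(x, geometry)

        def rot(a):
            return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

        p = np.zeros(2)
        R = np.eye(2)
        oracle = []
        for li, th in zip(geometry.lengths, theta):
            R = R @ rot(th)
            p = p + R @ np.array([0.0, -li])
            oracle.append(p.copy())
        assert np.allclose(pos["elbow"], oracle[0], atol=1e-12)
        assert np.allclose(pos["wrist"], oracle[1], atol=1e-12)
        assert np.allclose(pos["hand"], oracle[2], atol=1e-12)


@given(st.lists(st.floats(-np.pi, np.pi), min_size=3, max_size=3))
@settings(max_examples=50, deadline=None)
def test_forearm_length_preserved_for_all_postures(angles):
    geo = ArmGeometry()
    x = np.concatenate([angles, np.zeros(3)])
    pos = forward_kinematics(x, geo)
    assert np.isclose(np.linalg.norm(pos["wrist"] - pos["elbow"]),
                      geo.lengths[1], rtol=0, atol=1e-12)


# ----------------------------------------------------------------- dynamics

def test_no_forces_no_motion():
    geo = ArmGeometry(g=0.0)
    dyn = derive_eom(geo, JointLimits.disabled())
    x0 = np.array([0.3, -0.2, 0.5, 0, 0, 0.0])
    traj = simulate(dyn, lambda t, x: np.zeros(3), x0, 2.0)
    assert np.allclose(traj.x, x0[None, :], atol=1e-9)


def test_mass_matrix_dynamic_block_spd(dyn):
    rng = np.random.default_rng(7)
    for _ in range(100):
        x = np.concatenate([rng.uniform(-np.pi, np.pi, 3),
                            rng.uniform(-5, 5, 3)])
        M = dyn.mass_matrix(x)[3:, 3:]
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(M) > 0)


def test_passive_energy_conserved(dyn_free):
    rng = np.random.default_rng(3)
    for _ in range(5):
        x0 = np.concatenate([rng.uniform(-1.5, 1.5, 3),
                             rng.uniform(-1, 1, 3)])
        traj = simulate(dyn_free, lambda t, x: np.zeros(3), x0, 5.0)
        E = np.array([dyn_free.total_energy(x) for x in traj.x])
        assert np.abs(E - E[0]).max() / abs(E[0]) < 1e-3


def test_distal_light_arm_matches_single_pendulum():
    """With near-massless distal segments, joint 1 obeys the single-pendulum
    equation I_pivot th'' = -m1 g c1 sin(th) + tau1 (independent integrator)."""
    from scipy.integrate import solve_ivp

    eps = 1e-7
    geo = ArmGeometry(masses=(1.96, eps, eps),
                      inertias=(0.0147, eps * 0.26 ** 2 / 12,
                                eps * 0.08 ** 2 / 12))
    dyn = derive_eom(geo, JointLimits.disabled())
    tau1 = 0.8
    x0 = np.array([0.4, 0.0, 0.0, 0, 0, 0.0])
    traj = simulate(dyn, lambda t, x: np.array([tau1, 0.0, 0.0]), x0, 3.0)

    m1, c1, I1, g = geo.masses[0], geo.com[0], geo.inertias[0], geo.g
    I_pivot = I1 + m1 * c1 ** 2

    def pend(t, y):
        return [y[1], (tau1 - m1 * g * c1 * np.sin(y[0])) / I_pivot]

    sol = solve_ivp(pend, (0, 3.0), [0.4, 0.0], t_eval=traj.t,
                    rtol=1e-10, atol=1e-12)
    assert np.abs(traj.x[:, 0] - sol.y[0]).max() < 1e-5


def test_equations_match_sympy_lagrangian_oracle(geometry):
    """Independent symbolic derivation of the same chain via Lagrange's
    equations (sympy.physics.mechanics) agrees with the closed-form rhs."""
    import sympy as sp
    import sympy.physics.mechanics as me

    q = me.dynamicsymbols("q1:4")
    u = [qi.diff() for qi in q]
    tau = sp.symbols("tau1:4")
    N = me.ReferenceFrame("N")
    t = me.dynamicsymbols._t

    frames, bodies, loads = [], [], []
    O = me.Point("O")
    O.set_vel(N, 0)
    phi = 0
    tip_vec = 0 * N.x
    for i in range(3):
        phi = phi + q[i]
        A = N.orientnew(f"A{i}", "Axis", (phi, N.z))
        li = geometry.lengths[i]
        ci = geometry.com[i]
        mi = geometry.masses[i]
        Ii = geometry.inertias[i]
        direction = sp.sin(phi) * N.x - sp.cos(phi) * N.y
        com_vec = tip_vec + ci * direction
        com = O.locatenew(f"G{i}", com_vec)
        com.set_vel(N, com_vec.dt(N))
        inertia = me.inertia(A, 0, 0, Ii)
        bodies.append(me.RigidBody(f"B{i}", com, A, mi, (inertia, com)))
        loads.append((com, -mi * geometry.g * N.y))
        tip_vec = tip_vec + li * direction
        frames.append(A)
    # joint torques act between adjacent frames
    loads.append((frames[0], tau[0] * N.z - tau[1] * N.z))
    loads.append((frames[1], tau[1] * N.z - tau[2] * N.z))
    loads.append((frames[2], tau[2] * N.z))

    L = me.Lagrangian(N, *bodies)
    lm = me.LagrangesMethod(L, q, forcelist=loads, frame=N)
    lm.form_lagranges_equations()
    mass = lm.mass_matrix
    forcing = lm.forcing
    syms = list(q) + list(u) + list(tau)
    f_mass = sp.lambdify(syms, mass, "numpy")
    f_forc = sp.lambdify(syms, forcing, "numpy")

    dyn = derive_eom(geometry, JointLimits.disabled())
    rng = np.random.default_rng(11)
    for _ in range(5):
        x = np.concatenate([rng.uniform(-2, 2, 3), rng.uniform(-3, 3, 3)])
        c = rng.uniform(-5, 5, 3)
        args = list(x[:3]) + list(x[3:]) + list(c)
        qdd = np.linalg.solve(np.asarray(f_mass(*args), float),
                              np.asarray(f_forc(*args), float).ravel())
        ours = dyn.derivative(x, c)[3:]
        assert np.allclose(ours, qdd, rtol=1e-9, atol=1e-9)


# ------------------------------------------------------------ linearization

def test_linearization_kinematic_structure(linsys):
    assert np.allclose(linsys.A[:3, 3:], np.eye(3), atol=1e-14)
    assert np.allclose(linsys.A[:3, :3], 0.0, atol=1e-14)
    assert np.allclose(linsys.A[3:, 3:], 0.0, atol=1e-14)
    assert np.allclose(linsys.B[:3, :], 0.0, atol=1e-14)


def test_equilibrium_derivative_vanishes(dyn, linsys):
    f = dyn.derivative(linsys.x_star, linsys.c_star)
    assert np.abs(f).max() < 1e-10


def test_linearize_rejects_moving_point(dyn):
    with pytest.raises(ValueError):
        linearize(dyn, np.array([np.pi, 0, 0, 0.1, 0, 0.0]))


def test_jacobians_match_finite_differences(dyn, linsys):
    h = 1e-6
    A_fd = np.zeros((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        A_fd[:, j] = (dyn.derivative(linsys.x_star + e, linsys.c_star)
                      - dyn.derivative(linsys.x_star - e, linsys.c_star)) / (2 * h)
    B_fd = np.zeros((6, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        B_fd[:, j] = (dyn.derivative(linsys.x_star, linsys.c_star + e)
                      - dyn.derivative(linsys.x_star, linsys.c_star - e)) / (2 * h)
    assert np.all(np.abs(A_fd - linsys.A) <= 1e-5 * (1.0 + np.abs(linsys.A)))
    assert np.all(np.abs(B_fd - linsys.B) <= 1e-5 * (1.0 + np.abs(linsys.B)))


def test_upright_single_link_is_unstable_with_closed_form_rate():
    """Near-massless distal links reduce A's velocity-row angle entry to the
    inverted-pendulum value +m1 g c1 / (I1 + m1 c1^2)."""
    eps = 1e-10
    geo = ArmGeometry(masses=(1.96, eps, eps),
                      inertias=(0.0147, eps * 0.26 ** 2 / 12,
                                eps * 0.08 ** 2 / 12))
    dyn = derive_eom(geo, JointLimits.disabled())
    lin = linearize(dyn, ARM_UP)
    m1, c1, I1 = geo.masses[0], geo.com[0], geo.inertias[0]
    expected = m1 * geo.g * c1 / (I1 + m1 * c1 ** 2)
    assert expected > 0
    assert np.isclose(lin.A[3, 0], expected, rtol=1e-6)


def test_nonlinear_flow_agrees_with_linear_flow_to_second_order(dyn, linsys):
    """Over 10 ms the flow mismatch scales as O(||delta||^2): the slope of a
    log-log fit across perturbation sizes must be at least 1.9."""
    from scipy.linalg import expm

    T = 0.01
    Phi = expm(linsys.A * T)
    rng = np.random.default_rng(5)
    # sizes large enough that the quadratic remainder dominates the
    # integrator's error floor, small enough to stay in the Taylor regime
    sizes = np.array([1e-3, 3e-3, 1e-2, 3e-2])
    slopes = []
    for _ in range(20):
        d = rng.normal(0, 1, 6)
        d /= np.linalg.norm(d)
        errs = []
        for s in sizes:
            x0 = linsys.x_star + s * d
            traj = simulate(dyn, lambda t, x: linsys.c_star, x0, T, dt=T,
                            rtol=1e-11, atol=1e-13)
            lin_end = linsys.x_star + Phi @ (s * d)
            errs.append(np.linalg.norm(traj.x[-1] - lin_end) + 1e-18)
        slope = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        slopes.append(slope)
    assert min(slopes) >= 1.9


# ------------------------------------------------------------------ simulate

def test_equilibrium_start_stays_stationary(dyn, linsys):
    traj = simulate(dyn, lambda t, x: linsys.c_star, linsys.x_star, 1.0)
    assert np.abs(traj.x - linsys.x_star[None, :]).max() < 1e-8


def test_grid_independence_of_adaptive_solution(dyn_free):
    x0 = np.array([0.5, 0.3, -0.2, 0, 0, 0.0])
    t1 = simulate(dyn_free, lambda t, x: np.zeros(3), x0, 2.0, dt=1 / 60)
    t2 = simulate(dyn_free, lambda t, x: np.zeros(3), x0, 2.0, dt=1 / 120)
    assert np.abs(t1.x - t2.x[::2]).max() < 1e-6


def test_trajectory_validation():
    geo = ArmGeometry()
    with pytest.raises(ValueError):
        Trajectory(t=np.array([0.0, 0.1, 0.15]), x=np.zeros((3, 6)),
                   torque=np.zeros((3, 3)), geometry=geo)
    with pytest.raises(ValueError):
        Trajectory(t=np.arange(3) / 60, x=np.zeros((3, 6)),
                   torque=np.zeros((2, 3)), geometry=geo)
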