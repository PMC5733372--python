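"""Optional compiled right-hand side for closed-loop candidate simulations.

The inverse fit evaluates thousands of closed-loop simulations of the
three-link plant; the pure-numpy right-hand side is dominated by small-array
overhead.  When numba is available the rhs below — algebraically identical
to ``NonlinearDynamics.derivative`` with the LQR feedback law (optionally
sinusoidally perturbed) substituted in — is compiled once and driven through
``scipy.integrate.odeint``.  Everything degrades gracefully to the generic
``solve_ivp`` path when numba is missing.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _cl_rhs(x, t, beta, wv, Iv, g, lo, hi, steep, scale, Km, x_star, c_star,
            kappa, gamma):
    theta = x[:3]
    omega = x[3:]
    phi = np.empty(3)
    phid = np.empty(3)
    phi[0] = theta[0]
    phi[1] = phi[0] + theta[1]
    phi[2] = phi[1] + theta[2]
    phid[0] = omega[0]
    phid[1] = phid[0] + omega[1]
    phid[2] = phid[1] + omega[2]

    # feedback on the (possibly perturbed) state
    d = np.empty(6)
    pert = kappa * np.cos(gamma * t) if kappa != 0.0 else 0.0
    for i in range(6):
        d[i] = x[i] + pert - x_star[i]
    tau = np.empty(3)
    for j in range(3):
        acc = c_star[j]
        for i in range(6):
            acc -= Km[j, i] * d[i]
        # sigmoid joint-range torque
        acc += scale * (1.0 / (1.0 + np.exp(steep * (theta[j] - lo[j])))
                        - 1.0 / (1.0 + np.exp(-steep * (theta[j] - hi[j]))))
        tau[j] = acc

    Mabs = np.empty((3, 3))
    bias = np.empty(3)
    for j in range(3):
        s = 0.0
        for k in range(3):
            dph = phi[j] - phi[k]
            Mabs[j, k] = beta[j, k] * np.cos(dph)
            s += beta[j, k] * np.sin(dph) * phid[k] * phid[k]
        Mabs[j, j] += Iv[j]
        bias[j] = s + g * wv[j] * np.sin(phi[j])

    # map to relative joint coordinates: Mrel = L' Mabs L, rhs = tau - L' bias
    Lb2 = bias[2]
    Lb1 = bias[1] + bias[2]
    Lb0 = bias[0] + Lb1
    Mrel = np.empty((3, 3))
    for j in range(3):
        for k in range(3):
            acc = 0.0
            for i in range(j, 3):
                for l in range(k, 3):
                    acc += Mabs[i, l]
            Mrel[j, k] = acc
    rhs = np.empty(3)
    rhs[0] = tau[0] - Lb0
    rhs[1] = tau[1] - Lb1
    rhs[2] = tau[2] - Lb2
    acc3 = np.linalg.solve(Mrel, rhs)
    out = np.empty(6)
    for i in range(3):
        out[i] = omega[i]
        out[3 + i] = acc3[i]
    return out


def closed_loop_rhs(dyn, linsys, K, kappa: float = 0.0, gamma: float = 0.0):
    """odeint-style rhs ``f(x, t)`` for the LQR-controlled plant, or None."""
    if not HAVE_NUMBA:
        return None
    beta = np.ascontiguousarray(dyn._beta)
    wv = np.ascontiguousarray(dyn._w)
    Iv = np.ascontiguousarray(dyn._I)
    lo = np.ascontiguousarray(np.asarray(dyn.limits.lower, float))
    hi = np.ascontiguousarray(np.asarray(dyn.limits.upper, float))
    Km = np.ascontiguousarray(K.K if hasattr(K, "K") else np.asarray(K, float))
    x_star = np.ascontiguousarray(linsys.x_star)
    c_star = np.ascontiguousarray(linsys.c_star)
    g = float(dyn.geometry.g)
    steep = float(dyn.limits.steepness)
    scale = float(dyn.limits.scale)

    def rhs(x, t):
        return _cl_rhs(x, t, beta, wv, Iv, g, lo, hi, steep, scale,
                       Km, x_star, c_star, kappa, gamma)

    return rhs
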