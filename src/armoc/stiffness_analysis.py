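"""Principal directions of velocity resistance in the feedback gain.

The LQR torque ``tau = K x`` splits into an angle block and a velocity
block, ``tau = K1 x1 + K2 x2``.  The velocity direction most resisted by
the controller is the unit vector ``x2*`` maximizing ``||K2 x2||``; since
``K2`` is in general not symmetric, the exact maximizer is the leading
right singular vector of ``K2`` and the maximum is its leading singular
value ``tau*``.  When ``K2`` happens to be symmetric this coincides with
the principal eigenvector; the eigen-spectrum is reported alongside for
that reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lqr_control import GainMatrix

__all__ = ["StiffnessReport", "partition_gain", "principal_resistance",
           "stiffness_report"]


@dataclass(frozen=True)
class StiffnessReport:
    """Gain partition plus the principal velocity-resistance analysis."""

    K1: np.ndarray
    K2: np.ndarray
    x2_star: np.ndarray        # unit velocity direction most resisted
    tau_star: float            # max ||K2 x2|| over unit x2
    spectrum: np.ndarray       # singular values of K2, descending
    eigenvalues: np.ndarray    # eigenvalues of K2, by descending |.|

    def to_dict(self) -> dict:
        return {
            "K1": self.K1.tolist(),
            "K2": self.K2.tolist(),
            "x2_star": self.x2_star.tolist(),
            "tau_star": self.tau_star,
            "spectrum": self.spectrum.tolist(),
            "eigenvalues_real": np.real(self.eigenvalues).tolist(),
            "eigenvalues_imag": np.imag(self.eigenvalues).tolist(),
        }


def partition_gain(K: GainMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 3x6 gain into its angle (K1) and velocity (K2) blocks."""
    Km = K.K if isinstance(K, GainMatrix) else np.asarray(K, float)
    if Km.shape != (3, 6):
        raise ValueError(f"gain must be 3x6, got {Km.shape}")
    return Km[:, :3].copy(), Km[:, 3:].copy()


def principal_resistance(K2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(tau*, x2*, singular spectrum) of the velocity-feedback block.

    ``tau* = max_{||x2||=1} ||K2 x2||`` is the leading singular value and
    ``x2*`` the corresponding right singular direction (defined up to sign;
    the convention here makes its largest-magnitude component positive).
    """
    K2 = np.asarray(K2, float)
    if not np.all(np.isfinite(K2)):
        raise ValueError("K2 contains non-finite entries")
    _, s, Vt = np.linalg.svd(K2)
    x2 = Vt[0]
    k = int(np.argmax(np.abs(x2)))
    if x2[k] < 0:
        x2 = -x2
    return float(s[0]), x2, s


def stiffness_report(K: GainMatrix | np.ndarray) -> StiffnessReport:
    """Full stiffness analysis of a feedback gain."""
    K1, K2 = partition_gain(K)
    tau_star, x2_star, spectrum = principal_resistance(K2)
    eigvals = np.linalg.eigvals(K2)
    order = np.argsort(-np.abs(eigvals))
    return StiffnessReport(K1=K1, K2=K2, x2_star=x2_star, tau_star=tau_star,
                           spectrum=spectrum, eigenvalues=eigvals[order])
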