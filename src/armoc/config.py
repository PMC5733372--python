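"""YAML configuration for the command-line workflow.

A config file can override the anthropometric plant, joint limits, target
posture, solver tolerances and fit options; every key is optional and
defaults match the library defaults.  Angles are given in degrees at this
boundary and converted to radians internally.
"""

from __future__ import annotations

import numpy as np
import yaml

from .arm_model import ArmGeometry, JointLimits
from .inverse_oc import FitOptions

__all__ = ["load_config", "geometry_from_config", "limits_from_config",
           "fit_options_from_config", "DEFAULTS"]

DEFAULTS: dict = {
    "body_mass_kg": 70.0,
    "gravity": 9.81,
    "segment_lengths_m": None,       # None -> measured from the recording
    "joint_limits": {
        "lower_deg": [-60.0, 0.0, -70.0],
        "upper_deg": [200.0, 150.0, 80.0],
        "steepness": 30.0,
        "scale_nm": 5.0,
    },
    "fit": {
        "plant": "hybrid",
        "magnitude": "profile",
        "magnitude_center": 7.0,
        "match_processing": True,
        "log_bounds": [3.0, 9.0],
        "start": [6.0, 6.0],
        "restarts": 3,
        "maxiter": 400,
        "seed": 0,
        "onset_threshold_m": 0.02,
        "end_trim_s": 0.25,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config merged over the defaults (path may be None)."""
    if path is None:
        return _merge(DEFAULTS, {})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, user)


def geometry_from_config(cfg: dict, lengths=None) -> ArmGeometry:
    lengths = lengths or cfg.get("segment_lengths_m") or (0.30, 0.26, 0.08)
    return ArmGeometry.from_anthropometry(
        body_mass=cfg["body_mass_kg"], lengths=tuple(lengths),
        g=cfg["gravity"])


def limits_from_config(cfg: dict) -> JointLimits:
    jl = cfg["joint_limits"]
    deg = np.pi / 180.0
    return JointLimits(lower=tuple(v * deg for v in jl["lower_deg"]),
                       upper=tuple(v * deg for v in jl["upper_deg"]),
                       steepness=jl["steepness"], scale=jl["scale_nm"])


def fit_options_from_config(cfg: dict) -> FitOptions:
    f = cfg["fit"]
    return FitOptions(plant=f["plant"],
                      magnitude=f["magnitude"],
                      magnitude_center=f["magnitude_center"],
                      match_processing=f["match_processing"],
                      log_bounds=tuple(f["log_bounds"]),
                      start=tuple(f["start"]),
                      restarts=f["restarts"], maxiter=f["maxiter"],
                      seed=f["seed"], body_mass=cfg["body_mass_kg"],
                      onset_threshold=f["onset_threshold_m"],
                      end_trim=f["end_trim_s"])
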