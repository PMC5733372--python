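import numpy as np
import pytest

from armoc import (ArmGeometry, JointLimits, PRESET_NORMAL, PRESET_PATIENT,
                   SyntheticSpec, derive_eom, generate_recording, linearize,
                   lqr_gain)
from armoc.kinect_io import ingest_recording

ARM_UP = np.array([np.pi, 0.0, 0.0, 0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def geometry():
    return ArmGeometry()


@pytest.fixture(scope="session")
def limits():
    return JointLimits()


@pytest.fixture(scope="session")
def dyn(geometry, limits):
    return derive_eom(geometry, limits)


@pytest.fixture(scope="session")
def dyn_free(geometry):
    """Plant with the joint-range constraint switched off."""
    return derive_eom(geometry, JointLimits.disabled())


@pytest.fixture(scope="session")
def linsys(dyn):
    """Linearization about the raised (gravitationally unstable) target."""
    return linearize(dyn, ARM_UP)


@pytest.fixture(scope="session")
def gain_normal(linsys):
    K, S = lqr_gain(linsys, PRESET_NORMAL)
    return K


@pytest.fixture(scope="session")
def gain_patient(linsys):
    K, S = lqr_gain(linsys, PRESET_PATIENT)
    return K


@pytest.fixture(scope="session")
def noiseless_recording():
    """One noiseless synthetic flexion recording at the control-group preset."""
    spec = SyntheticSpec(weights=PRESET_NORMAL, noise_sigma=0.0, seed=0)
    return generate_recording(spec)


@pytest.fixture(scope="session")
def noiseless_smi(noiseless_recording):
    rec, _ = noiseless_recording
    return ingest_recording(rec)
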