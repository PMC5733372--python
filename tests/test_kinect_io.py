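"""Recording I/O, spectral resampling, scaling and angle extraction."""

import numpy as np
import pytest

from armoc import (ArmGeometry, PRESET_NORMAL, SyntheticSpec,
                   generate_recording, read_skeleton, resample_to_60fps,
                   segment_lengths, write_skeleton)
from armoc.kinect_io import (REQUIRED_JOINTS, SkeletonRecording,
                             extract_planar_angles, ingest_recording,
                             motion_window)
from armoc.synthetic_data import render_markers


def _static_recording(n=180, lengths=(0.30, 0.26, 0.08), noise=0.0, seed=0,
                      fps=30.0):
    theta = np.zeros((n, 3))
    markers = render_markers(theta, ArmGeometry(lengths=lengths))
    if noise > 0:
        markers = markers + np.random.default_rng(seed).normal(
            0, noise, markers.shape)
    positions = {j: markers[:, k, :] for k, j in enumerate(REQUIRED_JOINTS)}
    return SkeletonRecording(time=np.arange(n) / fps, positions=positions,
                             fps=fps)


# ------------------------------------------------------------------- I/O

def test_round_trip_preserves_coordinates(tmp_path, noiseless_recording):
    rec, _ = noiseless_recording
    path = tmp_path / "rec.csv"
    write_skeleton(rec, path)
    back = read_skeleton(path)
    assert back.n_frames == rec.n_frames
    for j in REQUIRED_JOINTS:
        assert np.abs(back.positions[j] - rec.positions[j]).max() < 1e-9


def test_missing_joint_named_in_error(tmp_path, noiseless_recording):
    import pandas as pd
    rec, _ = noiseless_recording
    path = tmp_path / "rec.csv"
    write_skeleton(rec, path)
    df = pd.read_csv(path)
    df[df.joint != "wrist"].to_csv(tmp_path / "nowrist.csv", index=False)
    with pytest.raises(ValueError, match="wrist"):
        read_skeleton(tmp_path / "nowrist.csv")


def test_unknown_joint_ignored_with_warning(tmp_path):
    import pandas as pd
    rec = _static_recording(150)
    path = tmp_path / "rec.csv"
    write_skeleton(rec, path)
    df = pd.read_csv(path)
    extra = df[df.joint == "wrist"].assign(joint="hip")
    pd.concat([df, extra]).to_csv(path, index=False)
    with pytest.warns(UserWarning, match="hip"):
        back = read_skeleton(path)
    assert set(back.positions) == set(REQUIRED_JOINTS)


def test_unparseable_rows_reported(tmp_path):
    rec = _static_recording(150)
    path = tmp_path / "rec.csv"
    write_skeleton(rec, path)
    text = path.read_text().splitlines()
    text[3] = text[3].replace(text[3].split(",")[2], "not_a_number", 1)
    path.write_text("\n".join(text))
    with pytest.raises(ValueError, match="line"):
        read_skeleton(path)


# -------------------------------------------------------------- resampling

def test_resample_doubles_frame_count():
    rec = _static_recording(150)
    out = resample_to_60fps(rec)
    assert out.n_frames == 300
    assert np.isclose(out.fps, 60.0)


def test_constant_channel_stays_constant():
    rec = _static_recording(150)
    out = resample_to_60fps(rec)
    for j in REQUIRED_JOINTS:
        assert np.allclose(out.positions[j], rec.positions[j][0][None, :],
                           atol=1e-12)


def test_bandlimited_sinusoid_resampled_exactly():
    """A 2 Hz tone spanning an integer number of periods on the 30 fps grid
    is reproduced at 60 fps to machine-level accuracy by the Fourier method."""
    n = 150
    t30 = np.arange(n) / 30.0
    rec = _static_recording(n)
    wave = 0.05 * np.sin(2 * np.pi * 2.0 * t30)
    for j in REQUIRED_JOINTS:
        rec.positions[j] = rec.positions[j].copy()
        rec.positions[j][:, 1] += wave
    out = resample_to_60fps(rec)
    t60 = np.arange(2 * n) / 60.0
    expected = 0.05 * np.sin(2 * np.pi * 2.0 * t60)
    got = out.positions["wrist"][:, 1] - rec.positions["wrist"][0, 1]
    assert np.abs(got[5:-5] - expected[5:-5]).max() < 1e-6


def test_resample_preserves_energy_of_bandlimited_input():
    """Parseval: spectral zero-padding preserves the mean-square content."""
    n = 150
    t30 = np.arange(n) / 30.0
    rec = _static_recording(n)
    wave = 0.05 * np.sin(2 * np.pi * 2.0 * t30)
    rec.positions["wrist"] = rec.positions["wrist"].copy()
    rec.positions["wrist"][:, 1] += wave
    out = resample_to_60fps(rec)
    y30 = rec.positions["wrist"][:, 1] - rec.positions["wrist"][0, 1]
    y60 = out.positions["wrist"][:, 1] - rec.positions["wrist"][0, 1]
    assert abs(np.mean(y60 ** 2) - np.mean(y30 ** 2)) < 1e-6


def test_nonuniform_input_rejected():
    rec = _static_recording(150)
    bad_time = rec.time.copy()
    bad_time[60:] += 0.5 / 30.0 * 1.2
    bad = SkeletonRecording(time=bad_time, positions=rec.positions, fps=30.0)
    with pytest.raises(ValueError, match="[Nn]on-uniform"):
        resample_to_60fps(bad)


# --------------------------------------------------------- segment lengths

def test_noiseless_static_lengths_exact():
    rec = _static_recording(180, lengths=(0.30, 0.26, 0.08))
    l = segment_lengths(rec)
    assert np.allclose(l, (0.30, 0.26, 0.08), atol=1e-12)


def test_static_window_frame_count():
    rec = _static_recording(180)
    mask = (rec.time - rec.time[0]) < 5.0
    assert mask.sum() == 150


def test_window_longer_than_recording_rejected():
    rec = _static_recording(60)
    with pytest.raises(ValueError):
        segment_lengths(rec, static_window=5.0)


def test_noisy_length_recovery_within_one_mm():
    """3 mm isotropic marker noise, mean-of-frames estimator, 20 seeds."""
    errs = []
    for seed in range(20):
        rec = _static_recording(150, noise=0.003, seed=seed)
        l = segment_lengths(rec)
        errs.append(np.abs(np.asarray(l) - (0.30, 0.26, 0.08)).max())
    assert np.mean(errs) < 1e-3
    assert np.max(errs) < 2e-3


# --------------------------------------------------------- angle extraction

def test_straight_down_arm_gives_zero_angles():
    rec = _static_recording(180)
    # add a small planar wobble so the motion plane is defined
    rec.positions["wrist"] = rec.positions["wrist"].copy()
    rec.positions["wrist"][:, 0] += 1e-6 * np.sin(np.arange(180))
    smi = extract_planar_angles(rec)
    assert np.abs(smi.theta).max() < 1e-4


def test_ninety_degree_flexion_recovered():
    theta = np.tile([np.pi / 2, 0.0, 0.0], (180, 1))
    markers = render_markers(theta, ArmGeometry())
    positions = {j: markers[:, k, :] for k, j in enumerate(REQUIRED_JOINTS)}
    rec = SkeletonRecording(time=np.arange(180) / 30.0, positions=positions,
                            fps=30.0)
    smi = extract_planar_angles(rec)
    assert np.allclose(smi.theta, [np.pi / 2, 0.0, 0.0], atol=1e-10)


def test_left_side_mirroring_keeps_flexion_positive():
    """A recording captured with flexion toward -x extracts identically."""
    rec, _ = generate_recording(
        SyntheticSpec(weights=PRESET_NORMAL, noise_sigma=0.0, seed=0))
    mirrored = SkeletonRecording(
        time=rec.time,
        positions={j: rec.positions[j] * np.array([-1.0, 1.0, 1.0])
                   for j in REQUIRED_JOINTS},
        fps=rec.fps)
    a = extract_planar_angles(rec)
    b = extract_planar_angles(mirrored)
    assert np.allclose(a.theta, b.theta, atol=1e-10)


def test_render_extract_round_trip(noiseless_recording, noiseless_smi,
                                   geometry):
    """Markers rendered from a simulated flexion are inverted back to the
    generating angle series (<0.5 deg RMS) and wrist height (<2 mm RMS)."""
    rec, truth = noiseless_recording
    smi = noiseless_smi
    # compare on the motion portion, excluding spectral edge samples
    n_static = 300                        # 5 s at 60 fps
    m = truth.x.shape[0]
    got = smi.theta[n_static:n_static + m][30:-30]
    want = truth.x[30:m - 30, :3]
    rms_deg = np.degrees(np.sqrt(np.mean((got - want) ** 2)))
    assert rms_deg < 0.5
    from armoc import forward_kinematics
    y_want = forward_kinematics(truth.x, geometry)["wrist"][:, 1]
    y_want = y_want - y_want[0]
    y_got = smi.wrist_y[n_static:n_static + m][30:-30]
    rms_mm = 1e3 * np.sqrt(np.mean((y_got - y_want[30:m - 30]) ** 2))
    assert rms_mm < 2.0


def test_motion_window_brackets_the_movement(noiseless_smi):
    i0, i_end = motion_window(noiseless_smi)
    assert 290 <= i0 <= 305                 # true onset at sample 300
    assert i_end == noiseless_smi.time.size - 15


def test_ingest_uses_raw_frames_for_lengths(noiseless_recording):
    rec, _ = noiseless_recording
    smi = ingest_recording(rec)
    assert np.allclose(smi.lengths, ArmGeometry().lengths, atol=1e-9)
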