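"""Reading, resampling and scaling of motion-capture skeleton recordings.

A recording is a long-format CSV with header ``time_s,joint,x_m,y_m,z_m``
(one row per joint per frame) holding the 3-D positions of the shoulder,
elbow, wrist and hand markers of one arm at a nominal 30 fps.  The capture
frame has +y pointing up; the sagittal motion plane is found from the
wrist's horizontal displacement, and joint angles follow the package's
convention (shoulder angle from the downward vertical, elbow and wrist
relative to the proximal segment, flexion positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import resample as _fourier_resample

__all__ = [
    "REQUIRED_JOINTS",
    "SkeletonRecording",
    "ScaledModelInput",
    "read_skeleton",
    "write_skeleton",
    "resample_to_60fps",
    "segment_lengths",
    "extract_planar_angles",
    "ingest_recording",
    "motion_window",
]

REQUIRED_JOINTS = ("shoulder", "elbow", "wrist", "hand")


@dataclass
class SkeletonRecording:
    """Per-frame 3-D positions of the four arm markers.

    Attributes
    ----------
    time : ndarray, shape (N,)
        Frame timestamps in seconds, nondecreasing.
    positions : dict of str -> ndarray (N, 3)
        Marker positions in metres for each required joint.
    fps : float
        Nominal frame rate.
    subject_id, side : str
        Optional metadata.
    """

    time: np.ndarray
    positions: dict[str, np.ndarray]
    fps: float = 30.0
    subject_id: str = ""
    side: str = "left"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        if np.any(np.diff(self.time) < 0):
            raise ValueError("timestamps must be nondecreasing")
        for j in REQUIRED_JOINTS:
            if j not in self.positions:
                raise ValueError(f"recording is missing required joint '{j}'")
            p = np.asarray(self.positions[j], float)
            if p.shape != (self.time.size, 3):
                raise ValueError(f"joint '{j}' must have one 3-D row per frame")
            if not np.all(np.isfinite(p)):
                raise ValueError(f"joint '{j}' contains non-finite positions")
            self.positions[j] = p

    @property
    def n_frames(self) -> int:
        return self.time.size

    def is_uniform(self, rtol: float = 1e-3) -> bool:
        dt = np.diff(self.time)
        return dt.size == 0 or bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-9))


@dataclass
class ScaledModelInput:
    """Subject-scaled planar model input extracted from a recording.

    Holds the measured segment lengths, the 60 fps planar joint-angle series
    and the wrist vertical displacement (relative to its initial, static
    position) that serves as the trajectory-matching error signal.
    """

    lengths: tuple[float, float, float]
    time: np.ndarray
    theta: np.ndarray          # (N, 3) joint angles, rad
    wrist_y: np.ndarray        # (N,) vertical wrist displacement, m
    fps: float = 60.0
    flagged_frames: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.theta = np.asarray(self.theta, float)
        self.wrist_y = np.asarray(self.wrist_y, float)
        if not all(l > 0 for l in self.lengths):
            raise ValueError("segment lengths must be positive")
        n = self.time.size
        if self.theta.shape != (n, 3) or self.wrist_y.shape != (n,):
            raise ValueError("angle and wrist series must match the time grid")


def read_skeleton(path, fps: float = 30.0, subject_id: str = "",
                  side: str = "left") -> SkeletonRecording:
    """Read a long-format marker CSV into a validated recording.

    Unknown joint names are ignored with a warning; missing required joints
    or unparseable rows raise with the offending entries named.
    """
    df = pd.read_csv(path)
    expected = {"time_s", "joint", "x_m", "y_m", "z_m"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    bad = df[["time_s", "x_m", "y_m", "z_m"]].apply(
        pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable rows at lines {lines}")
    unknown = sorted(set(df["joint"]) - set(REQUIRED_JOINTS))
    if unknown:
        warnings.warn(f"{path}: ignoring unknown joints {unknown}", stacklevel=2)
        df = df[df["joint"].isin(REQUIRED_JOINTS)]
    missing = [j for j in REQUIRED_JOINTS if j not in set(df["joint"])]
    if missing:
        raise ValueError(f"{path}: missing required joints {missing}")
    time = np.sort(df["time_s"].unique())
    positions = {}
    for j in REQUIRED_JOINTS:
        sub = df[df["joint"] == j].sort_values("time_s")
        if sub.shape[0] != time.size:
            raise ValueError(
                f"{path}: joint '{j}' has {sub.shape[0]} rows for "
                f"{time.size} frames")
        positions[j] = sub[["x_m", "y_m", "z_m"]].to_numpy(float)
    return SkeletonRecording(time=time, positions=positions, fps=fps,
                             subject_id=subject_id, side=side)


def write_skeleton(rec: SkeletonRecording, path) -> None:
    """Write a recording to the long-format CSV dialect."""
    rows = []
    for j in REQUIRED_JOINTS:
        p = rec.positions[j]
        rows.append(pd.DataFrame({
            "time_s": rec.time, "joint": j,
            "x_m": p[:, 0], "y_m": p[:, 1], "z_m": p[:, 2]}))
    out = pd.concat(rows).sort_values(["time_s", "joint"], kind="stable")
    out.to_csv(path, index=False, float_format="%.12g")


def _fill_gaps(time: np.ndarray, pos: np.ndarray, fps: float):
    """Re-grid onto the nominal uniform clock, linearly interpolating gaps."""
    n = int(round((time[-1] - time[0]) * fps)) + 1
    grid = time[0] + np.arange(n) / fps
    out = np.column_stack([np.interp(grid, time, pos[:, k]) for k in range(3)])
    return grid, out


def resample_to_60fps(rec: SkeletonRecording) -> SkeletonRecording:
    """Fourier (FFT zero-padding) resampling of a 30 fps recording to 60 fps.

    Each coordinate channel is resampled spectrally from N to exactly 2N
    samples.  Dropped frames are linearly interpolated onto the nominal
    30 fps clock first; a recording whose timestamps cannot be reconciled
    with a uniform grid is rejected.
    """
    if rec.n_frames < 4:
        raise ValueError("too few frames to resample")
    dt = np.diff(rec.time)
    nominal = 1.0 / rec.fps
    if np.any(np.abs(dt - nominal) > 0.51 * nominal):
        raise ValueError(
            "non-uniform frame times; fill gaps before Fourier resampling")
    positions = {}
    n_new = None
    for j in REQUIRED_JOINTS:
        grid, p = _fill_gaps(rec.time, rec.positions[j], rec.fps)
        res = _fourier_resample(p, 2 * p.shape[0], axis=0)
        positions[j] = res
        n_new = res.shape[0]
    time = rec.time[0] + np.arange(n_new) / (2 * rec.fps)
    return SkeletonRecording(time=time, positions=positions, fps=2 * rec.fps,
                             subject_id=rec.subject_id, side=rec.side)


def segment_lengths(rec: SkeletonRecording,
                    static_window: float = 5.0) -> tuple[float, float, float]:
    """Mean segment lengths over the initial static window.

    Per-frame Euclidean distances shoulder-elbow, elbow-wrist and wrist-hand
    are averaged over all frames with ``t - t0 < static_window`` (exactly
    150 frames for the default 5 s window at 30 fps).
    """
    mask = (rec.time - rec.time[0]) < static_window
    duration = rec.time[-1] - rec.time[0] + 1.0 / rec.fps
    if not mask.any() or duration < static_window - 1e-9:
        raise ValueError(
            f"recording ({duration:.2f} s) is shorter than "
            f"the {static_window:.2f} s static window")
    pairs = [("shoulder", "elbow"), ("elbow", "wrist"), ("wrist", "hand")]
    out = []
    for a, b in pairs:
        d = np.linalg.norm(rec.positions[b][mask] - rec.positions[a][mask], axis=1)
        out.append(float(d.mean()))
    return tuple(out)


def _motion_plane_axis(wrist_local: np.ndarray) -> np.ndarray:
    """Unit horizontal axis (in the x-z plane) of dominant wrist motion."""
    h = wrist_local[:, [0, 2]]
    h = h - h.mean(axis=0)
    cov = h.T @ h
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    if np.linalg.norm(axis) < 1e-12 or not np.isfinite(axis).all():
        axis = np.array([1.0, 0.0])
    # orient the axis so the motion's mean projection is non-negative
    # (flexion positive regardless of left/right side)
    proj = wrist_local[:, [0, 2]] @ axis
    if proj.mean() - proj[0] < 0:
        axis = -axis
    return axis


def extract_planar_angles(rec: SkeletonRecording,
                          static_window: float = 5.0,
                          baseline_window: float = 0.5) -> ScaledModelInput:
    """Project markers on the sagittal plane and extract joint angles.

    The vertical axis is +y of the capture frame; the horizontal axis is the
    dominant direction of the wrist's horizontal displacement (sign chosen
    so that flexion is positive, which also mirrors left/right sides).
    Joint angles follow the package convention and are unwrapped over time.
    The wrist vertical displacement is reported relative to the median of
    the first ``baseline_window`` seconds.
    """
    shoulder = rec.positions["shoulder"]
    local = {j: rec.positions[j] - shoulder for j in REQUIRED_JOINTS}
    axis = _motion_plane_axis(local["wrist"])
    planar = {j: np.column_stack([local[j][:, [0, 2]] @ axis, local[j][:, 1]])
              for j in REQUIRED_JOINTS}

    segs = [planar["elbow"],
            planar["wrist"] - planar["elbow"],
            planar["hand"] - planar["wrist"]]
    phi = np.empty((rec.n_frames, 3))
    flagged = np.zeros(rec.n_frames, bool)
    for k, s in enumerate(segs):
        norm = np.linalg.norm(s, axis=1)
        bad = norm < 1e-3
        flagged |= bad
        raw = np.arctan2(s[:, 0], -s[:, 1])
        raw[bad] = np.nan
        if bad.any():
            ok = ~bad
            raw[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(ok), raw[ok])
        phi[:, k] = np.unwrap(raw)
    theta = np.column_stack([phi[:, 0], phi[:, 1] - phi[:, 0],
                             phi[:, 2] - phi[:, 1]])

    n_base = max(1, int(round(baseline_window * rec.fps)))
    wy = planar["wrist"][:, 1]
    wrist_y = wy - np.median(wy[:n_base])

    window = min(static_window, (rec.time[-1] - rec.time[0]) * 0.99)
    lengths = segment_lengths(rec, static_window=window)
    return ScaledModelInput(lengths=lengths, time=rec.time - rec.time[0],
                            theta=theta, wrist_y=wrist_y, fps=rec.fps,
                            flagged_frames=np.flatnonzero(flagged))


def ingest_recording(rec: SkeletonRecording,
                     static_window: float = 5.0) -> ScaledModelInput:
    """Full ingest: measure lengths on the raw frames, then resample.

    Segment lengths are averaged over the raw 30 fps static window — the
    spectral resampling stage adds small oscillatory interpolation error
    whose rectification would bias the length estimate — and the angle and
    wrist series are extracted from the 60 fps resampled recording.
    """
    from dataclasses import replace as _dc_replace

    lengths = segment_lengths(rec, static_window=static_window)
    smi = extract_planar_angles(resample_to_60fps(rec),
                                static_window=static_window)
    return _dc_replace(smi, lengths=lengths)


def motion_window(smi: ScaledModelInput, threshold: float = 0.02,
                  end_trim: float = 0.25) -> tuple[int, int]:
    """Indices ``(i_onset, i_end)`` bracketing the movement.

    The onset is the first sustained excursion of the wrist vertical
    displacement beyond ``threshold`` metres from its static baseline,
    backtracked to the last quiet sample; the end trims ``end_trim``
    seconds to keep spectral edge effects out of the matching window.
    """
    y = smi.wrist_y
    n = y.size
    n_base = max(1, int(round(0.5 * smi.fps)))
    base = np.median(y[:n_base])
    dev = np.abs(y - base)
    # anchor on an unambiguous *sustained* excursion first: isolated noise
    # blips above the low threshold (marker noise is correlated after
    # resampling) and the alternating-sign spectral edge ringing at the very
    # start of the record must not trigger a false onset
    hi_mask = (dev > max(5.0 * threshold, 0.1)).astype(int)
    win = 8
    runsum = np.convolve(hi_mask, np.ones(win, int), mode="full")[win - 1:]
    hi = np.flatnonzero(runsum >= 6)
    if hi.size:
        i_hi = int(hi[0])
        quiet = np.flatnonzero(dev[:i_hi] < threshold)
        if quiet.size == 0:
            raise ValueError("no quiet baseline before the movement")
        i0 = int(quiet[-1]) + 1
        # prefer a genuinely still sample if one sits close behind
        still = np.flatnonzero(dev[:i0] < threshold / 4.0)
        if still.size and i0 - still[-1] <= int(0.5 * smi.fps):
            i0 = int(still[-1]) + 1
    else:
        above = dev > threshold
        sustained = above & np.roll(above, -1) & np.roll(above, -2)
        sustained[-2:] = above[-2:]
        idx = np.flatnonzero(sustained)
        if idx.size == 0:
            raise ValueError(
                "no movement above threshold found in the recording")
        i0 = int(idx[0])
        quiet = np.flatnonzero(dev[:i0] < threshold / 4.0)
        if quiet.size:
            i0 = int(quiet[-1]) + 1
    i_end = n - int(round(end_trim * smi.fps))
    if i_end <= i0 + 10:
        raise ValueError("movement window is too short to fit")
    return i0, i_end
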