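"""Bow and arm kinematics from 3D marker trajectories.

The measurement model: a violinist's bow use is summarised per frame by the
contact point between the bow-hair segment (frog → tip) and the string
segment (bridge → scroll direction).  Two arclength coordinates — distance
of the contact point to the frog along the bow, and to the bridge along the
string — form the 2D "bowing curve" that is later compared between leader
and follower.  Right-arm joint angles (wrist, elbow, shoulder) are computed
from 3-marker clusters per body segment with fixed Euler sequences.

Units: millimetres, seconds, degrees.  Coordinate frames are right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig
from scipy.spatial.transform import Rotation

__all__ = [
    "MotionTrace",
    "AudioSignal",
    "BowKinematics",
    "JointAngles",
    "LoudnessEnvelope",
    "bow_contact_kinematics",
    "derivatives",
    "joint_angles",
    "loudness_envelope",
    "BOW_MARKERS",
    "ARM_SEGMENTS",
]

#: markers required for bow kinematics
BOW_MARKERS = ("bow_frog", "bow_tip", "violin_bridge", "violin_scroll")

#: body segments (proximal → distal order) and their 3-marker clusters
ARM_SEGMENTS = {
    "thorax": ("thorax_1", "thorax_2", "thorax_3"),
    "upper_arm": ("upper_arm_1", "upper_arm_2", "upper_arm_3"),
    "forearm": ("forearm_1", "forearm_2", "forearm_3"),
    "hand": ("hand_1", "hand_2", "hand_3"),
}


@dataclass
class MotionTrace:
    """Timestamped 3D marker positions (mm) on a uniform time base."""

    time: np.ndarray
    markers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        n = self.time.shape[0]
        if self.time.ndim != 1:
            raise ValueError("time must be 1-D")
        for name, pos in self.markers.items():
            if pos.shape != (n, 3):
                raise ValueError(
                    f"marker {name!r} has shape {pos.shape}, expected ({n}, 3)"
                )
        if n > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform time base")

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        if self.n_frames < 2:
            return float("nan")
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_frames else 0.0

    def require(self, names) -> None:
        missing = [m for m in names if m not in self.markers]
        if missing:
            raise KeyError(f"missing markers: {missing}")

    def copy(self) -> "MotionTrace":
        return MotionTrace(self.time.copy(), {k: v.copy() for k, v in self.markers.items()})


@dataclass
class AudioSignal:
    """Mono audio sharing t=0 with its paired :class:`MotionTrace`."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.rate


@dataclass
class BowKinematics:
    """Per-frame bow contact-point coordinates and derivatives.

    ``dist_frog`` is the arclength from the frog to the bow-side contact
    point (mm), ``dist_bridge`` from the bridge to the string-side contact
    point (mm), ``tilt_angle`` the angle between bow and string axes (deg).
    """

    time: np.ndarray
    dist_frog: np.ndarray
    dist_bridge: np.ndarray
    tilt_angle: np.ndarray
    bow_velocity: np.ndarray | None = None
    bow_acceleration: np.ndarray | None = None
    bow_jerk: np.ndarray | None = None

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]


@dataclass
class JointAngles:
    """ISB-style right-arm joint angles (deg) and angular velocities (deg/s)."""

    time: np.ndarray
    angles: dict[str, np.ndarray] = field(default_factory=dict)
    velocities: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class LoudnessEnvelope:
    """Linear RMS amplitude evaluated on the motion-frame time grid."""

    time: np.ndarray
    loudness: np.ndarray
    f0: np.ndarray | None = None


# ---------------------------------------------------------------------------
# contact-point geometry


def _closest_segment_points(p1, q1, p2, q2):
    """Closest points between segments [p1,q1] and [p2,q2], vectorised.

    Returns (s, t): the clamped parameters along each segment in [0, 1].
    Standard quadratic minimisation with clamping (Ericson's algorithm).
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, (b * f - c * e) / denom, 0.0)
    s = np.clip(s, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b * s + f) / e
    # re-clamp and recompute s for boundary-active t
    t_cl = np.clip(t, 0.0, 1.0)
    redo = t != t_cl
    if np.any(redo):
        s_new = np.clip((t_cl * b - c) / a, 0.0, 1.0)
        s = np.where(redo, s_new, s)
    return s, t_cl


def bow_contact_kinematics(
    trace: MotionTrace,
    bow_length: float = 650.0,
    string_length: float = 330.0,
) -> BowKinematics:
    """Contact-point distances to frog and bridge, and bow-string tilt.

    The bow axis is the marker segment frog → tip; the string axis starts at
    the bridge and runs toward the scroll, truncated to ``string_length``.
    The contact point is the pair of closest points between the two
    segments.  Distances are clamped to the physical segment ranges.
    """
    trace.require(BOW_MARKERS)
    frog = trace.markers["bow_frog"]
    tip = trace.markers["bow_tip"]
    bridge = trace.markers["violin_bridge"]
    scroll = trace.markers["violin_scroll"]
    if not all(np.isfinite(m).all() for m in (frog, tip, bridge, scroll)):
        raise ValueError("non-finite marker coordinates (gaps?) in bow markers")

    bow_axis = tip - frog
    bow_norm = np.linalg.norm(bow_axis, axis=1)
    string_dir = scroll - bridge
    string_norm = np.linalg.norm(string_dir, axis=1)
    if np.any(bow_norm < 1e-9) or np.any(string_norm < 1e-9):
        raise ValueError("collinear markers: degenerate bow or string axis")

    string_end = bridge + string_dir / string_norm[:, None] * string_length
    s, t = _closest_segment_points(frog, tip, bridge, string_end)
    dist_frog = np.clip(s * bow_norm, 0.0, bow_length)
    dist_bridge = np.clip(t * string_length, 0.0, string_length)

    cosang = np.einsum("ij,ij->i", bow_axis, string_dir) / (bow_norm * string_norm)
    tilt = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    return BowKinematics(
        time=trace.time.copy(),
        dist_frog=dist_frog,
        dist_bridge=dist_bridge,
        tilt_angle=tilt,
    )


# ---------------------------------------------------------------------------
# smoothing and derivatives


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; identity when cutoff is None."""
    if cutoff is None:
        return np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    sos = _sig.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(3 * (2 * order + 1), x.shape[0] - 1)
    return _sig.sosfiltfilt(sos, x, padlen=padlen)


def derivatives(kin: BowKinematics, cutoff: float | None = 12.0) -> BowKinematics:
    """Fill bow velocity / acceleration / jerk from ``dist_frog``.

    The position signal is low-pass filtered (4th-order zero-phase
    Butterworth, default 12 Hz — above bowing frequency content) and then
    differentiated by central differences, one-sided at the endpoints.
    """
    if kin.n_frames < 9:
        raise ValueError("need >= 9 frames for differentiation")
    fs = kin.rate
    pos = _lowpass(kin.dist_frog, fs, cutoff)
    vel = np.gradient(pos, kin.time)
    acc = np.gradient(vel, kin.time)
    jerk = np.gradient(acc, kin.time)
    return replace(
        kin,
        bow_velocity=vel,
        bow_acceleration=acc,
        bow_jerk=jerk,
    )


# ---------------------------------------------------------------------------
# joint angles


def _cluster_frames(trace: MotionTrace, segment: str) -> np.ndarray:
    """Orthonormal frame (n, 3, 3) from a 3-marker cluster; columns = axes."""
    names = ARM_SEGMENTS[segment]
    trace.require(names)
    p1, p2, p3 = (trace.markers[n] for n in names)
    x = p2 - p1
    v = p3 - p1
    z = np.cross(x, v)
    zn = np.linalg.norm(z, axis=1)
    xn = np.linalg.norm(x, axis=1)
    if np.any(xn < 1e-9) or np.any(zn < 1e-6 * np.maximum(xn, 1.0)):
        raise ValueError(f"degenerate (collinear) marker cluster for segment {segment!r}")
    x = x / xn[:, None]
    z = z / zn[:, None]
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)


#: Euler sequence (intrinsic) and angle names per joint: (proximal, distal, seq, names)
_JOINTS = [
    ("thorax", "upper_arm", "YXY", ("shoulder_AA", "shoulder_E", "shoulder_PS")),
    ("upper_arm", "forearm", "ZXY", ("elbow_FE", "elbow_carrying", "elbow_PS")),
    ("forearm", "hand", "ZXY", ("wrist_FE", "wrist_AA", "wrist_PS")),
]


def joint_angles(trace: MotionTrace, cutoff: float | None = 12.0) -> JointAngles:
    """Right-arm joint angles by Euler decomposition of distal-in-proximal rotation.

    Shoulder uses a Y–X–Y sequence (plane of elevation, elevation, axial
    rotation); elbow and wrist use Z–X–Y (flexion-extension first).  Angular
    velocities are computed by differencing the unwrapped angle series.
    """
    frames = {seg: _cluster_frames(trace, seg) for seg in ARM_SEGMENTS}
    out = JointAngles(time=trace.time.copy())
    fs = trace.rate
    for prox, dist, seq, names in _JOINTS:
        r_rel = np.matmul(np.swapaxes(frames[prox], 1, 2), frames[dist])
        ang = Rotation.from_matrix(r_rel).as_euler(seq, degrees=True)
        if ang.ndim == 1:
            ang = ang[None, :]
        for j, name in enumerate(names):
            if name == "elbow_carrying":
                continue  # carried implicitly; not a reported angle
            a = ang[:, j]
            out.angles[name] = a
            if trace.n_frames >= 9:
                au = np.unwrap(np.radians(a))
                au = _lowpass(np.degrees(au), fs, cutoff) if cutoff else np.degrees(au)
                out.velocities[name] = np.gradient(au, trace.time)
            else:
                out.velocities[name] = np.zeros_like(a)
    return out


# ---------------------------------------------------------------------------
# loudness


def loudness_envelope(
    audio: AudioSignal,
    trace: MotionTrace,
    window: float = 0.05,
    compute_f0: bool = False,
    f0_range: tuple[float, float] = (80.0, 2000.0),
) -> LoudnessEnvelope:
    """RMS amplitude in centred windows evaluated at each motion frame.

    Linear amplitude (not dB): the downstream loudness gate is a ratio
    against the median, and ratio gating is scale-invariant only on a
    linear scale.  ``compute_f0`` adds an autocorrelation-based fundamental
    frequency estimate for voiced (non-silent) frames.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if audio.duration < trace.duration - 0.5 / trace.rate:
        raise ValueError(
            f"audio ({audio.duration:.3f} s) shorter than motion span "
            f"({trace.duration:.3f} s)"
        )
    x = audio.samples
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    half = window / 2.0
    lo = np.clip(np.round((trace.time - half) * audio.rate).astype(int), 0, x.shape[0])
    hi = np.clip(np.round((trace.time + half) * audio.rate).astype(int), 0, x.shape[0])
    cnt = np.maximum(hi - lo, 1)
    rms = np.sqrt((csum[hi] - csum[lo]) / cnt)

    f0 = None
    if compute_f0:
        f0 = np.full(trace.n_frames, np.nan)
        thresh = 0.05 * rms.max() if rms.max() > 0 else np.inf
        lag_min = max(int(audio.rate / f0_range[1]), 1)
        lag_max = int(audio.rate / f0_range[0])
        for i in range(trace.n_frames):
            if rms[i] < thresh or hi[i] - lo[i] < 2 * lag_max:
                continue
            seg = x[lo[i] : hi[i]]
            seg = seg - seg.mean()
            ac = _sig.correlate(seg, seg, mode="full")[seg.size - 1 :]
            if ac[0] <= 0:
                continue
            k = lag_min + int(np.argmax(ac[lag_min : lag_max + 1]))
            if 0 < k < ac.size - 1:  # parabolic refinement
                y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
                denom = y0 - 2 * y1 + y2
                delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                k = k + delta
            f0[i] = audio.rate / k
    return LoudnessEnvelope(time=trace.time.copy(), loudness=rms, f0=f0)
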