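"""Bow-stroke segmentation, gating, and leader/follower pairing.

Strokes are segmented from the *leader's* bow position: a stroke is a
maximal interval of movement in one direction, bounded by bow-velocity
reversals.  Two gates then select the analysable strokes: a length gate
(default: keep strokes whose excursion exceeds 150 mm) and a loudness gate
(default: keep strokes whose mean windowed RMS reaches at least 15 % of
the performance's median loudness).  Surviving leader windows are applied
verbatim — same clock-time frames — to the follower, and both 2D bowing
curves are resampled to a common number of points for shape comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .kinematics import BowKinematics, LoudnessEnvelope

__all__ = [
    "Stroke",
    "StrokePair",
    "segment_strokes",
    "gate_length",
    "gate_loudness",
    "pair_strokes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stroke:
    """One bow stroke as a half-open frame window [start_frame, end_frame)."""

    index: int
    start_frame: int
    end_frame: int
    direction: str  # "down" = increasing dist_frog, "up" = decreasing
    length: float  # |net change in dist_frog| over the window, mm
    duration: float  # s
    mean_loudness: float | None = None

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")


@dataclass
class StrokePair:
    """Matched leader/follower windows resampled to a common length."""

    stroke: Stroke
    avatar_curve: np.ndarray  # (N, 2): dist_frog, dist_bridge
    participant_curve: np.ndarray
    avatar_speed: np.ndarray  # (N,): |bow velocity|
    participant_speed: np.ndarray
    resample_rate: float  # Hz of the resampled profiles


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def segment_strokes(
    kin: BowKinematics,
    min_duration: float = 0.08,
    min_excursion: float = 10.0,
    speed_floor: float = 10.0,
) -> list[Stroke]:
    """Segment the bow-position signal into alternating strokes.

    Boundaries are placed at sign changes of bow velocity within moving
    intervals (|v| > ``speed_floor`` mm/s).  Hysteresis: candidate
    sub-strokes shorter than ``min_duration`` or with net excursion below
    ``min_excursion`` are merged into the neighbouring stroke — this
    suppresses tremor-induced micro-reversals.
    """
    if kin.bow_velocity is None:
        raise ValueError("bow velocity not computed; call derivatives() first")
    v = kin.bow_velocity
    if v.shape[0] == 0:
        return []
    pos = kin.dist_frog
    dt = 1.0 / kin.rate

    strokes: list[Stroke] = []
    for lo, hi in _runs(np.abs(v) > speed_floor):
        if hi - lo < 2:
            continue
        sign = np.where(v[lo:hi] >= 0, 1, -1)
        bounds = [lo] + list(lo + 1 + np.flatnonzero(np.diff(sign))) + [hi]
        segs = list(zip(bounds[:-1], bounds[1:]))
        segs = _merge_segments(segs, pos, dt, min_duration, min_excursion)
        for s, e in segs:
            net = pos[e - 1] - pos[s]
            strokes.append(
                Stroke(
                    index=-1,
                    start_frame=int(s),
                    end_frame=int(e),
                    direction="down" if net >= 0 else "up",
                    length=float(abs(net)),
                    duration=(e - s) * dt,
                )
            )
    return [replace(st, index=i) for i, st in enumerate(strokes)]


def _merge_segments(segs, pos, dt, min_duration, min_excursion):
    """Iteratively merge sub-threshold segments into their neighbours."""

    def exc(s, e):
        return abs(pos[e - 1] - pos[s])

    segs = list(segs)
    while segs:
        scores = [((e - s) * dt, exc(s, e)) for s, e in segs]
        bad = [
            i
            for i, (dur, ex) in enumerate(scores)
            if dur < min_duration or ex < min_excursion
        ]
        if not bad:
            break
        # merge the weakest offender first
        i = min(bad, key=lambda k: scores[k][1])
        if len(segs) == 1:
            return []
        if i == 0:
            j = 1
        elif i == len(segs) - 1:
            j = i - 1
        else:
            j = i - 1 if scores[i - 1][1] >= scores[i + 1][1] else i + 1
        a, b = sorted((i, j))
        segs[a] = (segs[a][0], segs[b][1])
        del segs[b]
    return segs


def gate_length(strokes: list[Stroke], min_length: float = 150.0) -> list[Stroke]:
    """Keep strokes whose excursion strictly exceeds ``min_length`` mm."""
    return [s for s in strokes if s.length > min_length]


def gate_loudness(
    strokes: list[Stroke],
    env: LoudnessEnvelope,
    fraction: float = 0.15,
) -> list[Stroke]:
    """Keep strokes whose mean in-window loudness reaches ``fraction`` of the
    performance's median per-frame loudness.

    The reference is the median over *all* frames of the performance (the
    gate runs before any cross-performance pooling).  Returned strokes have
    ``mean_loudness`` filled in.
    """
    ref = float(np.median(env.loudness))
    if not np.any(env.loudness > 0):
        raise ValueError("silent performance: all-zero loudness envelope")
    out = []
    for s in strokes:
        mean_loud = float(np.mean(env.loudness[s.start_frame : s.end_frame]))
        if mean_loud >= fraction * ref:
            out.append(replace(s, mean_loudness=mean_loud))
    return out


def pair_strokes(
    avatar_kin: BowKinematics,
    participant_kin: BowKinematics,
    strokes: list[Stroke],
    n_resample: int = 100,
) -> list[StrokePair]:
    """Extract identical clock-time windows from both performers and resample.

    Each surviving leader stroke window is applied to both kinematics; the
    2D curves (dist_frog, dist_bridge) and absolute-speed profiles are
    linearly interpolated in time onto ``n_resample`` points.  Pairs whose
    window extends past the follower trace are dropped with a warning.
    """
    if avatar_kin.bow_velocity is None or participant_kin.bow_velocity is None:
        raise ValueError("bow velocity not computed on both performers")
    pairs = []
    for st in strokes:
        if st.end_frame > participant_kin.n_frames:
            log.warning(
                "stroke %d window [%d, %d) exceeds participant trace (%d frames); dropped",
                st.index,
                st.start_frame,
                st.end_frame,
                participant_kin.n_frames,
            )
            continue
        sl = slice(st.start_frame, st.end_frame)
        t = avatar_kin.time[sl]
        tq = np.linspace(t[0], t[-1], n_resample)

        def rs(x, src_t=t, q=tq):
            return np.interp(q, src_t, x)

        a_curve = np.column_stack([rs(avatar_kin.dist_frog[sl]), rs(avatar_kin.dist_bridge[sl])])
        p_curve = np.column_stack(
            [rs(participant_kin.dist_frog[sl]), rs(participant_kin.dist_bridge[sl])]
        )
        pairs.append(
            StrokePair(
                stroke=st,
                avatar_curve=a_curve,
                participant_curve=p_curve,
                avatar_speed=rs(np.abs(avatar_kin.bow_velocity[sl])),
                participant_speed=rs(np.abs(participant_kin.bow_velocity[sl])),
                resample_rate=(n_resample - 1) / (t[-1] - t[0]),
            )
        )
    return pairs
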