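"""Synthetic leader/follower performances, cohort designs and questionnaires.

The generator emulates the statistical structure the analysis assumes: a
leader ("avatar") plays a score of alternating bow strokes with smooth
minimum-jerk speed profiles and stroke-gated audio; a follower
("participant") tracks the leader's bow kinematics with controllable
fidelity — tracking lag, gain error, constant offset, low-passed spatial
noise, and a high-frequency tremor that degrades smoothness.  A cohort
design assigns participants to pieces/violin sections and applies
condition-dependent fidelity and latent-presence effects, returning a
ground-truth ledger so recovery can be tested end-to-end.

Every artifact is a deterministic function of its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.spatial.transform import Rotation

from .kinematics import AudioSignal, MotionTrace, bow_contact_kinematics

__all__ = [
    "StrokeEvent",
    "ScoreSpec",
    "FidelityParams",
    "ConditionEffect",
    "ParticipantProfile",
    "CohortDesign",
    "CohortBundle",
    "CellSpec",
    "generate_avatar",
    "generate_follower",
    "generate_cohort",
    "generate_questionnaires",
    "default_design",
    "LIKERT_RANGES",
]

BOW_LENGTH = 650.0  # mm, frog to tip
STRING_LENGTH = 330.0  # mm, bridge toward scroll

#: Likert ranges per questionnaire scale
LIKERT_RANGES = {"WPQ": (1, 7), "MPQS": (1, 5), "MPQP": (1, 5)}

#: latent scale means (baseline condition) per questionnaire scale
_SCALE_BASE = {"WPQ": 4.6, "MPQS": 3.1, "MPQP": 2.8}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StrokeEvent:
    direction: str  # "up" | "down"
    length: float  # mm
    duration: float  # s
    dynamic: float = 0.8  # relative amplitude 0-1
    rest_after: float = 0.0  # s


@dataclass
class ScoreSpec:
    """An abstract piece: an ordered list of bow strokes."""

    strokes: list[StrokeEvent]
    sample_rate_motion: float = 120.0
    sample_rate_audio: float = 48000.0

    def __post_init__(self):
        prev = None
        for ev in self.strokes:
            if ev.direction not in ("up", "down"):
                raise ValueError(f"bad direction {ev.direction!r}")
            if ev.length <= 0 or ev.duration <= 0:
                raise ValueError("stroke lengths and durations must be > 0")
            if prev is not None and prev.rest_after == 0 and prev.direction == ev.direction:
                raise ValueError("directions must alternate unless separated by a rest")
            prev = ev

    @property
    def duration(self) -> float:
        return sum(ev.duration + ev.rest_after for ev in self.strokes)


@dataclass(frozen=True)
class FidelityParams:
    """Knobs controlling how faithfully the follower tracks the leader."""

    spatial_noise_sd: float = 0.0  # mm
    tracking_lag: float = 0.0  # s
    gain_error: float = 1.0  # multiplicative bias on stroke length
    offset: float = 0.0  # mm
    tremor_amp: float = 0.0  # mm
    tremor_freq: float = 8.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if self.spatial_noise_sd < 0:
            raise ValueError("spatial_noise_sd must be >= 0")

    @property
    def neutral(self) -> bool:
        return (
            self.spatial_noise_sd == 0
            and self.tracking_lag == 0
            and self.gain_error == 1.0
            and self.offset == 0
            and self.tremor_amp == 0
        )


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative/additive deltas a condition applies to baseline fidelity."""

    noise_scale: float = 1.0
    tremor_scale: float = 1.0
    lag_add: float = 0.0
    presence_shift: float = 0.0  # latent presence mean shift, Likert units

    @property
    def is_null(self) -> bool:
        return (
            self.noise_scale == 1.0
            and self.tremor_scale == 1.0
            and self.lag_add == 0.0
            and self.presence_shift == 0.0
        )


@dataclass(frozen=True)
class ParticipantProfile:
    id: int
    age: float
    years_played: float
    msi_score: float
    itq_score: float
    violin_section: int  # 1 | 2


# Table-style default assignment: violin section and the piece played in each
# condition, cycled for participants beyond eleven.
_SECTION_PATTERN = (1, 1, 2, 1, 2, 1, 2, 2, 1, 1, 2)
_PIECES = {1: ("holst", "dvorak3"), 2: ("dvorak1", "brahms")}
_PIECE_2D_FIRST = (True, True, False, False, False, False, True, True, False, True, True)


@dataclass
class CohortDesign:
    n_participants: int = 11
    conditions: tuple[str, ...] = ("2D", "3D")
    n_trials: int = 4
    piece_assignment: dict | None = None  # participant -> {condition: piece}
    violin_sections: dict | None = None  # participant -> 1|2
    condition_effects: dict[str, ConditionEffect] | None = None
    baseline: FidelityParams = field(
        default_factory=lambda: FidelityParams(
            spatial_noise_sd=4.0, tracking_lag=0.04, tremor_amp=1.5, tremor_freq=8.0
        )
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_trials < 1 or len(self.conditions) < 1:
            raise ValueError("design counts must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition labels")
        if self.violin_sections is None:
            self.violin_sections = {
                p: _SECTION_PATTERN[(p - 1) % len(_SECTION_PATTERN)]
                for p in self.participants
            }
        if self.piece_assignment is None:
            self.piece_assignment = {}
            for p in self.participants:
                pieces = _PIECES[self.violin_sections[p]]
                flip = _PIECE_2D_FIRST[(p - 1) % len(_PIECE_2D_FIRST)]
                order = pieces if flip else pieces[::-1]
                self.piece_assignment[p] = {
                    cond: order[i % 2] for i, cond in enumerate(self.conditions)
                }
        if self.condition_effects is None:
            # 2D rendering lacks stereoscopic depth cues: noisier, shakier
            # tracking and lower latent presence than the 3D baseline.
            self.condition_effects = {}
            for cond in self.conditions:
                if cond == "2D":
                    self.condition_effects[cond] = ConditionEffect(
                        noise_scale=1.5, tremor_scale=1.5, presence_shift=-0.6
                    )
                else:
                    self.condition_effects[cond] = ConditionEffect()
        missing = set(self.conditions) - set(self.condition_effects)
        if missing:
            raise ValueError(f"condition_effects missing conditions: {sorted(missing)}")

    @property
    def participants(self) -> list[int]:
        return list(range(1, self.n_participants + 1))

    @property
    def n_cells(self) -> int:
        return self.n_participants * len(self.conditions) * self.n_trials

    def cells(self):
        for p in self.participants:
            for cond in self.conditions:
                for t in range(1, self.n_trials + 1):
                    yield p, cond, t


# ---------------------------------------------------------------------------
# avatar generation


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk displacement profile x(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _bow_path(score: ScoreSpec, lead: float = 0.3):
    """Bow position (dist from frog, mm) and per-sample dynamic over time."""
    fs = score.sample_rate_motion
    total = score.duration + 2 * lead
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    s = np.zeros(n)
    dyn = np.zeros(n)
    pos = 0.0
    cursor = lead
    segments = []  # (t0, t1, sign*length, dynamic, start_pos)
    for ev in score.strokes:
        sgn = 1.0 if ev.direction == "down" else -1.0
        segments.append((cursor, cursor + ev.duration, sgn * ev.length, ev.dynamic, pos))
        pos += sgn * ev.length
        cursor += ev.duration + ev.rest_after
    # fill the sampled path
    s[:] = 0.0
    last_pos = 0.0
    for t0, t1, delta, dynamic, p0 in segments:
        i0, i1 = np.searchsorted(t, [t0, t1])
        tau = np.clip((t[i0:i1] - t0) / (t1 - t0), 0, 1)
        s[i0:i1] = p0 + delta * _min_jerk(tau)
        dyn[i0:i1] = dynamic
        s[i1:] = p0 + delta  # hold through the following rest
        last_pos = p0 + delta
    s[t >= segments[-1][1]] = last_pos
    # shift so the path sits comfortably inside the bow
    span = s.max() - s.min()
    usable = BOW_LENGTH - 60.0
    if span > usable:
        raise ValueError(f"score excursion {span:.0f} mm exceeds usable bow length")
    s = s - s.min() + 30.0 + (usable - span) / 2.0
    return t, s, dyn, segments


def _arm_pose(s: np.ndarray):
    """Map bow position to plausible shoulder/elbow/wrist Euler angles (deg)."""
    x = (s - BOW_LENGTH / 2) / (BOW_LENGTH / 2)  # roughly [-1, 1]
    shoulder = np.stack(
        [30.0 + 4.0 * x, -60.0 + 6.0 * x, 10.0 - 2.0 * x], axis=1
    )  # YXY: plane of elevation, elevation, axial
    elbow = np.stack([95.0 - 18.0 * x, 5.0 * np.ones_like(x), 20.0 + 6.0 * x], axis=1)
    wrist = np.stack([5.0 + 8.0 * x, 2.0 - 3.0 * x, np.zeros_like(x)], axis=1)
    return shoulder, elbow, wrist


_CLUSTER_TEMPLATE = np.array([[0.0, 0.0, 0.0], [60.0, 0.0, 0.0], [0.0, 60.0, 0.0]])


def _build_markers(time: np.ndarray, s: np.ndarray, y: np.ndarray) -> MotionTrace:
    """Marker set realising bow position ``s`` and bridge distance ``y``.

    Geometry: the violin is fixed with the bridge at the origin and the
    string axis along +y; the bow lies along +x and slides along its own
    axis, so the contact point sits ``s`` mm from the frog and ``y`` mm
    from the bridge.
    """
    n = time.shape[0]
    markers = {
        "violin_bridge": np.tile([0.0, 0.0, 0.0], (n, 1)),
        "violin_scroll": np.tile([0.0, STRING_LENGTH, 0.0], (n, 1)),
        "bow_frog": np.column_stack([-s, y, np.zeros(n)]),
        "bow_tip": np.column_stack([BOW_LENGTH - s, y, np.zeros(n)]),
    }
    # right-arm chain: thorax fixed; distal segments posed from bow position
    shoulder_origin = np.array([150.0, -250.0, 350.0])
    markers["thorax_1"] = np.tile(shoulder_origin + [-80.0, -60.0, -40.0], (n, 1))
    markers["thorax_2"] = markers["thorax_1"] + [80.0, 0.0, 0.0]
    markers["thorax_3"] = markers["thorax_1"] + [0.0, 80.0, 0.0]

    sh_ang, el_ang, wr_ang = _arm_pose(s)
    r_sh = Rotation.from_euler("YXY", sh_ang, degrees=True)
    r_el_rel = Rotation.from_euler("ZXY", el_ang, degrees=True)
    r_wr_rel = Rotation.from_euler("ZXY", wr_ang, degrees=True)
    r_el = r_sh * r_el_rel
    r_wr = r_el * r_wr_rel

    elbow_origin = shoulder_origin + r_sh.apply(np.tile([0.0, -280.0, 0.0], (n, 1)))
    wrist_origin = elbow_origin + r_el.apply(np.tile([0.0, -260.0, 0.0], (n, 1)))
    for seg, rot, origin in (
        ("upper_arm", r_sh, shoulder_origin + np.zeros((n, 3))),
        ("forearm", r_el, elbow_origin),
        ("hand", r_wr, wrist_origin),
    ):
        for j in range(3):
            markers[f"{seg}_{j + 1}"] = origin + rot.apply(
                np.tile(_CLUSTER_TEMPLATE[j], (n, 1))
            )
    return MotionTrace(time=time, markers=markers)


def generate_avatar(score: ScoreSpec, seed: int = 0) -> tuple[MotionTrace, AudioSignal]:
    """Render a leader performance: marker trajectories plus gated audio.

    Bow displacement within each stroke follows the minimum-jerk profile;
    the bridge distance wanders slowly so the 2D bowing curve is
    non-degenerate.  Audio is a 440 Hz tone whose amplitude equals the
    stroke's ``dynamic`` during strokes (10 ms ramps) and zero in rests.
    """
    if not score.strokes:
        raise ValueError("empty score")
    rng = np.random.default_rng(seed)
    t, s, dyn, segments = _bow_path(score)
    phase = rng.uniform(0, 2 * np.pi)
    y = 55.0 + 5.0 * np.sin(2 * np.pi * 0.3 * t + phase)
    trace = _build_markers(t, s, y)

    fa = score.sample_rate_audio
    n_audio = int(np.ceil(t[-1] * fa)) + 1
    ta = np.arange(n_audio) / fa
    env = np.zeros(n_audio)
    ramp = 0.01
    for t0, t1, _, dynamic, _ in segments:
        up = np.clip((ta - t0) / ramp, 0, 1)
        down = np.clip((t1 - ta) / ramp, 0, 1)
        env = np.maximum(env, dynamic * np.minimum(up, down) * ((ta >= t0) & (ta <= t1)))
    audio = AudioSignal(samples=env * np.sin(2 * np.pi * 440.0 * ta), rate=fa)
    return trace, audio


# ---------------------------------------------------------------------------
# follower generation


def generate_follower(avatar: MotionTrace, params: FidelityParams) -> MotionTrace:
    """Perturbed copy of the leader's bow kinematics, re-expressed as markers.

    The leader's bow-position signal is lagged, gain-scaled about its mean,
    offset, and perturbed with 20 Hz low-passed Gaussian noise plus a
    sinusoidal tremor; the marker set is rebuilt with the shared geometry.
    With all parameters neutral the follower equals the avatar exactly.
    """
    if params.neutral:
        return avatar.copy()
    t = avatar.time
    duration = t[-1] - t[0]
    if params.tracking_lag >= duration:
        raise ValueError("tracking lag exceeds performance duration")
    fs = 1.0 / (t[1] - t[0])
    if params.tremor_amp > 0 and params.tremor_freq >= fs / 2:
        raise ValueError("tremor frequency must be below the motion Nyquist rate")

    kin = bow_contact_kinematics(avatar, BOW_LENGTH, STRING_LENGTH)
    s_a, y_a = kin.dist_frog, kin.dist_bridge
    rng = np.random.default_rng(params.seed)

    s = np.interp(t - params.tracking_lag, t, s_a)
    y = np.interp(t - params.tracking_lag, t, y_a)
    s = s_a.mean() + params.gain_error * (s - s_a.mean()) + params.offset

    if params.spatial_noise_sd > 0:
        s = s + _smooth_noise(rng, t.shape[0], fs, params.spatial_noise_sd)
        y = y + _smooth_noise(rng, t.shape[0], fs, 0.5 * params.spatial_noise_sd)
    if params.tremor_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        s = s + params.tremor_amp * np.sin(2 * np.pi * params.tremor_freq * t + phase)
    s = np.clip(s, 0.0, BOW_LENGTH)
    y = np.clip(y, 5.0, STRING_LENGTH)
    return _build_markers(t.copy(), s, y)


def _smooth_noise(rng, n, fs, sd, cutoff=20.0):
    """Gaussian noise low-passed at ``cutoff`` Hz, rescaled to sd ``sd``."""
    white = rng.standard_normal(n)
    if cutoff < fs / 2 and n > 30:
        sos = _sig.butter(4, cutoff, btype="low", fs=fs, output="sos")
        white = _sig.sosfiltfilt(sos, white, padlen=min(27, n - 1))
        white = white / max(white.std(), 1e-12)
    return sd * white


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CellSpec:
    participant: int
    condition: str
    trial: int
    piece: str
    violin_section: int
    params: FidelityParams
    avatar_seed: int


@dataclass
class CohortBundle:
    """Cohort of leader/follower performances, realised lazily per cell."""

    design: CohortDesign
    profiles: list[ParticipantProfile]
    cells: list[CellSpec]
    scores: dict[str, ScoreSpec]
    ledger: pd.DataFrame  # ground-truth effects per cell

    def __post_init__(self):
        self._avatar_cache: dict[str, tuple[MotionTrace, AudioSignal]] = {}

    def realize_avatar(self, piece: str) -> tuple[MotionTrace, AudioSignal]:
        if piece not in self._avatar_cache:
            seed = _piece_seed(self.design.seed, piece)
            self._avatar_cache[piece] = generate_avatar(self.scores[piece], seed)
        return self._avatar_cache[piece]

    def realize(self, cell: CellSpec) -> tuple[MotionTrace, MotionTrace, AudioSignal]:
        leader, audio = self.realize_avatar(cell.piece)
        follower = generate_follower(leader, cell.params)
        return leader, follower, audio

    def iter_cells(self):
        for cell in self.cells:
            leader, follower, audio = self.realize(cell)
            yield cell, leader, follower, audio


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _piece_seed(root_seed: int, piece: str) -> int:
    h = np.random.SeedSequence([root_seed, _stable_hash(piece)])
    return int(h.generate_state(1)[0] % (2**31))


def _default_score(piece: str, root_seed: int) -> ScoreSpec:
    """An abstract piece: 12-16 alternating strokes with varied lengths."""
    rng = np.random.default_rng(np.random.SeedSequence([root_seed, 7, _stable_hash(piece)]))
    n = int(rng.integers(12, 17))
    usable = BOW_LENGTH - 90.0  # leave margin at frog and tip
    strokes = []
    direction = "down" if rng.random() < 0.5 else "up"
    pos, run_min, run_max = 0.0, 0.0, 0.0
    for _ in range(n):
        room = (
            usable - (pos - run_min) if direction == "down" else usable - (run_max - pos)
        )
        if room >= 220:
            length = float(rng.uniform(220, min(430, room)))
        else:
            length = float(rng.uniform(0.5, 0.95) * max(room, 120.0))
        strokes.append(
            StrokeEvent(
                direction=direction,
                length=length,
                duration=float(rng.uniform(0.45, 0.75)),
                dynamic=float(rng.uniform(0.5, 1.0)),
                rest_after=float(rng.choice([0.0, 0.0, 0.0, 0.3])),
            )
        )
        pos += length if direction == "down" else -length
        run_min, run_max = min(run_min, pos), max(run_max, pos)
        direction = "up" if direction == "down" else "down"
    return ScoreSpec(strokes=strokes)


def default_design(**overrides) -> CohortDesign:
    """The default cohort: 11 participants x 2 conditions x 4 trials."""
    return CohortDesign(**overrides)


def generate_cohort(design: CohortDesign) -> CohortBundle:
    """Realise a cohort design into per-cell performance specifications.

    Per-participant baseline fidelity is drawn from log-normal distributions
    (so noise magnitudes stay positive) around the design's baseline;
    condition effects scale those baselines.  The returned ledger records
    the realised parameters and the condition deltas (ground truth for
    recovery tests).
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    profiles = []
    for p in design.participants:
        profiles.append(
            ParticipantProfile(
                id=p,
                age=float(np.round(rng.uniform(18, 25), 1)),
                years_played=float(np.round(np.clip(rng.normal(14.7, 2.4), 12, 25), 1)),
                msi_score=float(np.round(np.clip(rng.normal(5.1, 0.4), 1, 7), 2)),
                itq_score=float(np.round(np.clip(rng.normal(4.2, 0.8), 1, 7), 2)),
                violin_section=design.violin_sections[p],
            )
        )
    base = design.baseline
    # per-participant multiplicative baselines, log-normal around the design baseline
    noise_mult = np.exp(rng.normal(0.0, 0.35, design.n_participants))
    tremor_mult = np.exp(rng.normal(0.0, 0.35, design.n_participants))
    lag_mult = np.exp(rng.normal(0.0, 0.25, design.n_participants))
    gain_base = np.exp(rng.normal(0.0, 0.03, design.n_participants))
    offset_base = rng.normal(0.0, 5.0, design.n_participants)

    cells, rows = [], []
    for p, cond, trial in design.cells():
        eff = design.condition_effects[cond]
        params = FidelityParams(
            spatial_noise_sd=base.spatial_noise_sd * noise_mult[p - 1] * eff.noise_scale,
            tracking_lag=base.tracking_lag * lag_mult[p - 1] + eff.lag_add,
            gain_error=gain_base[p - 1],
            offset=offset_base[p - 1],
            tremor_amp=base.tremor_amp * tremor_mult[p - 1] * eff.tremor_scale,
            tremor_freq=base.tremor_freq,
            seed=int(
                np.random.SeedSequence(
                    [design.seed, p, design.conditions.index(cond), trial]
                ).generate_state(1)[0]
                % (2**31)
            ),
        )
        piece = design.piece_assignment[p][cond]
        cell = CellSpec(
            participant=p,
            condition=cond,
            trial=trial,
            piece=piece,
            violin_section=design.violin_sections[p],
            params=params,
            avatar_seed=_piece_seed(design.seed, piece),
        )
        cells.append(cell)
        rows.append(
            {
                "participant": p,
                "condition": cond,
                "trial": trial,
                "piece": piece,
                "violin_section": cell.violin_section,
                "spatial_noise_sd": params.spatial_noise_sd,
                "tremor_amp": params.tremor_amp,
                "tracking_lag": params.tracking_lag,
                "gain_error": params.gain_error,
                "offset": params.offset,
                "delta_noise_scale": eff.noise_scale - 1.0,
                "delta_tremor_scale": eff.tremor_scale - 1.0,
                "delta_lag": eff.lag_add,
                "delta_presence": eff.presence_shift,
            }
        )
    pieces = {c.piece for c in cells}
    scores = {piece: _default_score(piece, design.seed) for piece in pieces}
    return CohortBundle(
        design=design,
        profiles=profiles,
        cells=cells,
        scores=scores,
        ledger=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# questionnaires


def generate_questionnaires(
    design: CohortDesign,
    n_items: dict[str, int] | None = None,
    reliability_target: float = 0.85,
) -> pd.DataFrame:
    """Simulate Likert questionnaire responses with known latent structure.

    Latent presence per administration = scale base + condition shift +
    participant offset + cell noise; items add independent noise whose
    variance is chosen (net of discretisation noise) so the expected
    Cronbach's alpha approximates ``reliability_target``.  WPQ items are on
    1-7, MPQS/MPQP on 1-5 (round-half-up, clipped); perceived difficulty is
    a continuous 0-100 rating driven by the piece.
    """
    if not 0 < reliability_target < 1:
        raise ValueError("reliability_target must be in (0, 1)")
    n_items = dict(n_items or {"WPQ": 6, "MPQS": 5, "MPQP": 5})
    for scale, k in n_items.items():
        if k < 2:
            raise ValueError(f"need >= 2 items per scale (got {k} for {scale!r})")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 23]))
    sd_participant, sd_cell = 0.5, 0.35
    var_latent = sd_participant**2 + sd_cell**2

    part_offsets = {
        scale: rng.normal(0, sd_participant, design.n_participants) for scale in n_items
    }
    piece_difficulty = {
        piece: rng.uniform(20, 70)
        for piece in {pc for m in design.piece_assignment.values() for pc in m.values()}
    }
    diff_offsets = rng.normal(0, 8.0, design.n_participants)

    rows = []
    for p, cond, trial in design.cells():
        shift = design.condition_effects[cond].presence_shift
        piece = design.piece_assignment[p][cond]
        row = {
            "participant": p,
            "condition": cond,
            "trial": trial,
            "piece": piece,
            "violin_section": design.violin_sections[p],
        }
        for scale, k in n_items.items():
            lo, hi_ = LIKERT_RANGES[scale]
            theta = _SCALE_BASE[scale] + shift + part_offsets[scale][p - 1]
            theta = theta + rng.normal(0, sd_cell)
            item_var = k * var_latent * (1 - reliability_target) / reliability_target
            item_var = max(item_var - 1.0 / 12.0, 1e-3)  # net of discretisation noise
            items = theta + rng.normal(0, np.sqrt(item_var), k)
            items = np.clip(np.floor(items + 0.5), lo, hi_)  # round half up
            for j, val in enumerate(items, 1):
                row[f"{scale}_{j}"] = float(val)
        row["difficulty"] = float(
            np.clip(
                piece_difficulty[piece] + diff_offsets[p - 1] + rng.normal(0, 6.0),
                0,
                100,
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)
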