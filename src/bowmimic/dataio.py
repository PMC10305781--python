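"""File formats and run configuration.

The native exchange formats are diffable text: a marker-trajectory TSV
dialect modelled on optical-capture exports (header lines, then one row
per frame with x/y/z per marker in mm), 16-bit PCM WAV for audio, CSV for
tables and JSON for configuration and manifests.  Occluded-marker gaps are
written as ``NA`` and rejected by the kinematics layer unless gap-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .kinematics import AudioSignal, MotionTrace

__all__ = [
    "read_motion",
    "write_motion",
    "read_audio",
    "write_audio",
    "RunConfig",
    "config_hash",
    "write_manifest",
]

_GAP = "NA"


def write_motion(trace: MotionTrace, path) -> None:
    """Write a trace in the marker-TSV dialect (mm, frame-indexed)."""
    path = Path(path)
    names = list(trace.markers)
    rate = trace.rate if trace.n_frames > 1 else 120.0
    with path.open("w") as fh:
        fh.write(f"NO_OF_FRAMES\t{trace.n_frames}\n")
        fh.write(f"NO_OF_MARKERS\t{len(names)}\n")
        fh.write(f"FREQUENCY\t{rate:.6f}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(names) + "\n")
        cols = ["frame"] + [f"{n}_{ax}" for n in names for ax in "xyz"]
        fh.write("\t".join(cols) + "\n")
        for i in range(trace.n_frames):
            vals = [str(i)]
            for n in names:
                for v in trace.markers[n][i]:
                    vals.append(_GAP if not np.isfinite(v) else repr(float(v)))
            fh.write("\t".join(vals) + "\n")


def read_motion(path) -> MotionTrace:
    """Read the marker-TSV dialect back into a :class:`MotionTrace`.

    Malformed headers, inconsistent row lengths and frame-count mismatches
    raise with the offending line number.  ``NA`` gaps become NaN.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()

    def fail(lineno, msg):
        raise ValueError(f"{path.name}:{lineno}: {msg}")

    header = {}
    try:
        for i, key in enumerate(("NO_OF_FRAMES", "NO_OF_MARKERS", "FREQUENCY")):
            k, _, v = lines[i].partition("\t")
            if k != key:
                fail(i + 1, f"expected header {key}, got {k!r}")
            header[key] = float(v)
        mk = lines[3].split("\t")
        if mk[0] != "MARKER_NAMES":
            fail(4, "expected MARKER_NAMES header")
        names = mk[1:]
    except IndexError:
        raise ValueError(f"{path.name}: truncated header")
    n_frames = int(header["NO_OF_FRAMES"])
    if len(names) != int(header["NO_OF_MARKERS"]):
        fail(4, "marker count does not match NO_OF_MARKERS")
    body = lines[5 : 5 + n_frames]
    if len(body) != n_frames:
        raise ValueError(
            f"{path.name}: declared {n_frames} frames but body has {len(body)} rows"
        )
    data = np.empty((n_frames, 3 * len(names)))
    for i, line in enumerate(body):
        parts = line.split("\t")
        if len(parts) != 1 + 3 * len(names):
            fail(6 + i, f"expected {1 + 3 * len(names)} columns, got {len(parts)}")
        data[i] = [np.nan if p == _GAP else float(p) for p in parts[1:]]
    time = np.arange(n_frames) / header["FREQUENCY"]
    markers = {
        n: data[:, 3 * j : 3 * j + 3].copy() for j, n in enumerate(names)
    }
    return MotionTrace(time=time, markers=markers)


def write_audio(audio: AudioSignal, path) -> None:
    """Write 16-bit PCM WAV."""
    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(str(path), int(audio.rate), np.round(x * 32767.0).astype(np.int16))


def read_audio(path) -> AudioSignal:
    """Read a PCM WAV as mono float in [-1, 1] (channels averaged)."""
    import warnings

    try:
        with warnings.catch_warnings():
            # a truncated data chunk must be an error, not a silent short read
            warnings.simplefilter("error", wavfile.WavFileWarning)
            rate, data = wavfile.read(str(path))
    except Exception as err:
        raise ValueError(f"unreadable WAV {path}: {err}") from err
    if data.dtype == np.int16:
        x = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(float)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioSignal(samples=x, rate=float(rate))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly via JSON.

    Threshold defaults are the reference protocol's stated values: 150 mm
    stroke-length gate and 15 % of the median loudness.
    """

    # cohort design
    n_participants: int = 11
    conditions: tuple[str, ...] = ("2D", "3D")
    n_trials: int = 4
    seed: int = 0
    # stroke segmentation and gates
    min_length: float = 150.0
    loudness_fraction: float = 0.15
    min_duration: float = 0.08
    min_excursion: float = 10.0
    speed_floor: float = 10.0
    gate_on: str = "avatar"  # whose audio the loudness gate uses
    # kinematics / metrics
    smoothing_cutoff: float = 12.0
    n_resample: int = 100
    sparc_fc: float = 10.0
    sparc_amp_threshold: float = 0.05
    sparc_pad_level: int = 4
    # model settings
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    compare: bool = True
    # paths
    out_dir: str = "results/pipeline"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["conditions"] = tuple(d.get("conditions", ("2D", "3D")))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, files, timings=None, counts=None) -> Path:
    """Write a manifest listing every output file with a content hash."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "files": {
            str(Path(f).relative_to(out_dir)): _sha256(Path(f)) for f in files
        },
        "timings_s": timings or {},
        "counts": counts or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
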