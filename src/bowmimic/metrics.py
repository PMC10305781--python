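"""Per-stroke imitation metrics.

Two quantities score how faithfully a follower reproduces a leader's bow
stroke:

* **PD** — the Procrustes distance between the two 2D bowing curves
  (dist_frog vs dist_bridge), i.e. the residual dissimilarity after the
  optimal translation, rotation/reflection and uniform scaling.  PD ∈ [0, 1];
  0 means identical shapes.
* **SPARC** — the spectral arc-length smoothness index of a speed profile:
  the negative arc length of the amplitude-normalised magnitude spectrum
  over an adaptively truncated low-frequency band.  Smoother movement gives
  a higher (less negative) value.  **dSI** is the follower-minus-leader
  difference in SPARC, so positive dSI means the follower moved more
  smoothly than the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StrokeMetrics", "procrustes_distance", "sparc", "stroke_metrics"]


@dataclass
class StrokeMetrics:
    """PD / SPARC outputs for one leader-follower stroke pair."""

    stroke_index: int
    pd: float
    si_avatar: float
    si_participant: float
    dsi: float
    length: float | None = None
    duration: float | None = None
    mean_loudness: float | None = None
    direction: str | None = None


def _standardize(curve: np.ndarray) -> np.ndarray:
    """Center at centroid and scale to unit Frobenius norm."""
    c = np.asarray(curve, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError(f"curve must be N x 2, got {c.shape}")
    if c.shape[0] < 3:
        raise ValueError("need at least 3 points")
    c = c - c.mean(axis=0)
    norm = np.linalg.norm(c)
    if norm < 1e-12:
        raise ValueError("zero-variance curve (all points identical)")
    return c / norm


def procrustes_distance(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
) -> float:
    """Procrustes distance between two matched N x 2 point sets.

    Both curves are centred and scaled to unit Frobenius norm; the optimal
    orthogonal alignment is found by SVD.  The returned value is the
    residual sum of squared distances after alignment with the optimal
    uniform scale, which for unit-norm configurations equals
    ``1 - (sum of singular values)**2`` and lies in [0, 1].  The measure is
    symmetric and invariant under similarity transforms of either curve.
    """
    a = _standardize(curve_a)
    b = _standardize(curve_b)
    if a.shape != b.shape:
        raise ValueError("curves must have the same number of points")
    u, s, vt = np.linalg.svd(a.T @ b)
    if not allow_reflection:
        # restrict to proper rotations: flip the smallest singular value
        # when the optimal orthogonal map is a reflection
        if np.linalg.det(u @ vt) < 0:
            s = s.copy()
            s[-1] = -s[-1]
    trace = s.sum()
    if allow_scaling:
        d = 1.0 - trace**2
    else:
        d = 2.0 * (1.0 - trace)
    return float(max(d, 0.0))


def sparc(
    speed: np.ndarray,
    fs: float,
    fc: float = 10.0,
    amp_threshold: float = 0.05,
    pad_level: int = 4,
) -> float:
    """Spectral arc-length smoothness of a speed profile.

    The speed profile's magnitude spectrum is computed with zero padding to
    ``2**(ceil(log2(N)) + pad_level)``, normalised by its DC value, limited
    to [0, fc] and adaptively truncated at the last frequency whose
    normalised magnitude still reaches ``amp_threshold``.  The result is
    the negative arc length of the normalised spectrum over that band with
    the frequency axis rescaled to [0, 1] — so the index is dimensionless,
    amplitude-invariant and (approximately) time-scale robust.
    """
    v = np.asarray(speed, dtype=float)
    if v.ndim != 1 or v.shape[0] < 8:
        raise ValueError("speed must be 1-D with at least 8 samples")
    if fs <= 2 * fc:
        raise ValueError(f"sampling rate {fs} must exceed 2*fc = {2 * fc}")
    if not np.any(v != 0):
        raise ValueError("zero speed profile")

    n_fft = 2 ** (int(np.ceil(np.log2(v.shape[0]))) + pad_level)
    spec = np.abs(np.fft.rfft(v, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    spec = spec / spec[0]

    sel = freqs <= fc
    freqs, spec = freqs[sel], spec[sel]
    above = np.nonzero(spec >= amp_threshold)[0]
    cut = above[-1] if above.size else spec.shape[0] - 1
    freqs, spec = freqs[: cut + 1], spec[: cut + 1]

    f_scaled = freqs / freqs[-1]
    arc = np.sum(np.sqrt(np.diff(f_scaled) ** 2 + np.diff(spec) ** 2))
    return float(-arc)


def stroke_metrics(pair, fs: float, **sparc_kwargs) -> StrokeMetrics:
    """PD and dSI for one :class:`~bowmimic.strokes.StrokePair`.

    ``fs`` is the effective sampling rate of the resampled profiles
    (``n_resample / stroke duration``).  dSI = SPARC(participant) −
    SPARC(avatar); errors from the constituent metrics are re-raised with
    the stroke index attached.
    """
    try:
        pd_val = procrustes_distance(pair.avatar_curve, pair.participant_curve)
        si_a = sparc(pair.avatar_speed, fs, **sparc_kwargs)
        si_p = sparc(pair.participant_speed, fs, **sparc_kwargs)
    except ValueError as err:
        raise ValueError(f"stroke {pair.stroke.index}: {err}") from err
    st = pair.stroke
    return StrokeMetrics(
        stroke_index=st.index,
        pd=pd_val,
        si_avatar=si_a,
        si_participant=si_p,
        dsi=si_p - si_a,
        length=st.length,
        duration=st.duration,
        mean_loudness=st.mean_loudness,
        direction=st.direction,
    )
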