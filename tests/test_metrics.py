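"""Procrustes-distance and SPARC metric properties and oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import procrustes as scipy_procrustes

from bowmimic.metrics import procrustes_distance, sparc, stroke_metrics
from bowmimic.strokes import Stroke, StrokePair


# --------------------------------------------------------------------------
# independent oracles


def procrustes_oracle(a, b, n_grid=8000):
    """Grid search over rotation angle and reflection; optimal scale closed
    form per angle.  Independent of the SVD path under test."""

    def std(c):
        c = np.asarray(c, float)
        c = c - c.mean(axis=0)
        return c / np.linalg.norm(c)

    A, B = std(a), std(b)
    theta = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    ct, s = np.cos(theta), np.sin(theta)
    best = -np.inf
    for refl in (1.0, -1.0):
        bx, by = B[:, 0], refl * B[:, 1]
        # <A, B R(theta)^T> as a function of theta
        inner = (
            A[:, 0][:, None] * (bx[:, None] * ct - by[:, None] * s)
            + A[:, 1][:, None] * (bx[:, None] * s + by[:, None] * ct)
        ).sum(axis=0)
        best = max(best, inner.max())
    return 1.0 - max(best, 0.0) ** 2


def sparc_oracle(v, fs, fc=10.0, amp_threshold=0.05, pad_level=4):
    """Spectral arc length by direct DTFT evaluation (no FFT), restricted to
    the [0, fc] band; trapezoidal arc length on the selected spectrum.
    Independent of the rfft-based path under test."""
    v = np.asarray(v, float)
    n = v.size
    n_fft = 2 ** (int(np.ceil(np.log2(n))) + pad_level)
    df = fs / n_fft
    freqs = np.arange(int(np.floor(fc / df)) + 1) * df
    j = np.arange(n)
    mag = np.empty(freqs.size)
    for lo in range(0, freqs.size, 4096):  # chunked to bound memory
        f_chunk = freqs[lo : lo + 4096]
        W = np.exp(-2j * np.pi * np.outer(f_chunk, j) / fs)
        mag[lo : lo + 4096] = np.abs(W @ v)
    mag = mag / mag[0]
    above = np.nonzero(mag >= amp_threshold)[0]
    freqs, mag = freqs[: above[-1] + 1], mag[: above[-1] + 1]
    f = freqs / freqs[-1]
    return -np.sum(np.sqrt(np.diff(f) ** 2 + np.diff(mag) ** 2))


def random_curve(rng, n=20):
    return rng.standard_normal((n, 2)).cumsum(axis=0)


def min_jerk_speed(n=120, fs=120.0, L=300.0, T=1.0):
    tau = np.linspace(0, 1, n)
    return L / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)


# --------------------------------------------------------------------------
# Procrustes distance


class TestProcrustes:
    def test_identity_and_similarity_invariance(self):
        rng = np.random.default_rng(0)
        a = random_curve(rng)
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = 2.7 * a @ R.T + np.array([15.0, -40.0])
        assert procrustes_distance(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_reflection_invariance_default(self):
        rng = np.random.default_rng(1)
        a = random_curve(rng)
        b = a * np.array([1.0, -1.0])
        assert procrustes_distance(a, b) == pytest.approx(0.0, abs=1e-10)
        assert procrustes_distance(a, b, allow_reflection=False) > 1e-3

    def test_unit_square_displaced_corner_matches_oracle(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        disp = sq.copy()
        disp[2] += [0.5, 0.0]
        got = procrustes_distance(sq, disp)
        assert got == pytest.approx(procrustes_oracle(sq, disp), abs=1e-4)
        assert 0 < got < 1

    @pytest.mark.parametrize("seed", range(8))
    def test_random_pairs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_curve(rng, 8), random_curve(rng, 8)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_oracle(a, b), abs=1e-4
        )

    def test_matches_scipy_disparity(self):
        # independent library cross-check of the same convention
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = random_curve(rng), random_curve(rng)
            _, _, disparity = scipy_procrustes(a, b)
            assert procrustes_distance(a, b) == pytest.approx(disparity, abs=1e-9)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b = random_curve(rng, 12), random_curve(rng, 12)
            d_ab = procrustes_distance(a, b)
            assert d_ab == pytest.approx(procrustes_distance(b, a), abs=1e-10)
            assert 0.0 <= d_ab <= 1.0

    def test_not_invariant_to_anisotropic_scaling_or_reordering(self):
        rng = np.random.default_rng(5)
        a = random_curve(rng)
        assert procrustes_distance(a, a * np.array([1.0, 3.0])) > 1e-4
        perm = rng.permutation(a.shape[0])
        assert procrustes_distance(a, a[perm]) > 1e-4

    def test_degenerate_inputs_raise(self):
        flat = np.zeros((5, 2))
        with pytest.raises(ValueError, match="zero-variance"):
            procrustes_distance(flat, np.random.default_rng(0).standard_normal((5, 2)))
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((4, 2)), np.zeros((5, 2)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10),
        tx=st.floats(-100, 100),
    )
    def test_similarity_invariance_property(self, seed, angle, scale, tx):
        rng = np.random.default_rng(seed)
        a = random_curve(rng, 10)
        b = random_curve(rng, 10)
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        b2 = scale * b @ R.T + np.array([tx, -tx])
        assert procrustes_distance(a, b2) == pytest.approx(
            procrustes_distance(a, b), abs=1e-9
        )


# --------------------------------------------------------------------------
# SPARC


class TestSparc:
    def test_amplitude_invariance(self):
        v = min_jerk_speed()
        for c in (0.1, 3.0, 1000.0):
            assert sparc(c * v, 120.0) == pytest.approx(sparc(v, 120.0), abs=1e-12)

    def test_matches_direct_dtft_oracle_at_defaults(self):
        # same definition, independently computed spectrum (direct DTFT)
        v = min_jerk_speed(n=120, fs=120.0)
        assert sparc(v, 120.0) == pytest.approx(
            sparc_oracle(v, 120.0, pad_level=4), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_oracle_random_profiles(self, seed):
        # at converged padding the discrete arc length matches a spectrum
        # oversampled a further 8x to well below 1e-3
        rng = np.random.default_rng(seed)
        base = min_jerk_speed(n=100 + 10 * seed)
        v = base + rng.uniform(0.02, 0.1) * base.max() * np.sin(
            2 * np.pi * rng.uniform(3, 9) * np.linspace(0, 1, base.size)
        )
        assert sparc(v, 120.0, pad_level=8) == pytest.approx(
            sparc_oracle(v, 120.0, pad_level=11), abs=1e-3
        )

    def test_ripple_degrades_smoothness(self):
        v = min_jerk_speed()
        t = np.linspace(0, 1, v.size)
        ripple = v + 0.1 * v.max() * np.sin(2 * np.pi * 8 * t)
        assert sparc(ripple, 120.0) < sparc(v, 120.0)

    def test_smooth_profile_below_minus_one(self):
        assert sparc(min_jerk_speed(), 120.0) <= -1.0

    def test_time_dilation_robustness(self):
        base = sparc(min_jerk_speed(n=120, T=1.0), 120.0)
        for dil in (0.5, 0.75, 1.5, 2.0):
            n = int(round(120 * dil))
            v = min_jerk_speed(n=n, T=dil)
            assert abs(sparc(v, 120.0) - base) < 0.05

    def test_errors(self):
        with pytest.raises(ValueError, match="zero speed"):
            sparc(np.zeros(100), 120.0)
        with pytest.raises(ValueError):
            sparc(min_jerk_speed(), 15.0)  # fs <= 2 fc
        with pytest.raises(ValueError):
            sparc(np.ones(4), 120.0)


# --------------------------------------------------------------------------
# stroke-level wrapper


def _make_pair(curve_a, curve_b, speed_a, speed_b):
    stroke = Stroke(
        index=0, start_frame=0, end_frame=100, direction="down", length=300.0, duration=1.0
    )
    return StrokePair(
        stroke=stroke,
        avatar_curve=curve_a,
        participant_curve=curve_b,
        avatar_speed=speed_a,
        participant_speed=speed_b,
        resample_rate=100.0,
    )


class TestStrokeMetrics:
    def test_identical_pair_gives_zero(self):
        rng = np.random.default_rng(0)
        curve = random_curve(rng, 100)
        v = min_jerk_speed(n=100)
        m = stroke_metrics(_make_pair(curve, curve.copy(), v, v.copy()), fs=100.0)
        assert m.pd == pytest.approx(0.0, abs=1e-12)
        assert m.dsi == 0.0

    def test_dsi_antisymmetry(self):
        rng = np.random.default_rng(1)
        curve = random_curve(rng, 100)
        va = min_jerk_speed(n=100)
        t = np.linspace(0, 1, 100)
        vb = va + 0.08 * va.max() * np.sin(2 * np.pi * 7 * t)
        m_ab = stroke_metrics(_make_pair(curve, curve, va, vb), fs=100.0)
        m_ba = stroke_metrics(_make_pair(curve, curve, vb, va), fs=100.0)
        assert m_ab.dsi == pytest.approx(-m_ba.dsi, abs=1e-14)
        assert m_ab.dsi < 0  # follower with tremor is less smooth

    def test_purity(self):
        rng = np.random.default_rng(2)
        pair = _make_pair(
            random_curve(rng, 100),
            random_curve(rng, 100),
            min_jerk_speed(n=100),
            min_jerk_speed(n=100) + 1.0,
        )
        m1 = stroke_metrics(pair, fs=100.0)
        m2 = stroke_metrics(pair, fs=100.0)
        assert (m1.pd, m1.si_avatar, m1.si_participant, m1.dsi) == (
            m2.pd,
            m2.si_avatar,
            m2.si_participant,
            m2.dsi,
        )

    def test_error_tags_stroke_index(self):
        pair = _make_pair(
            np.zeros((100, 2)), np.zeros((100, 2)), np.zeros(100), np.zeros(100)
        )
        with pytest.raises(ValueError, match="stroke 0"):
            stroke_metrics(pair, fs=100.0)
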