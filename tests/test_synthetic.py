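"""Generator contracts: avatar kinematics, follower fidelity knobs, cohort
design conservation, and questionnaire reliability."""

import numpy as np
import pandas as pd
import pytest

from bowmimic import pipeline
from bowmimic.kinematics import bow_contact_kinematics
from bowmimic.metrics import sparc
from bowmimic.stats import cronbach_alpha
from bowmimic.synthetic import (
    CohortDesign,
    ConditionEffect,
    FidelityParams,
    ScoreSpec,
    StrokeEvent,
    default_design,
    generate_avatar,
    generate_cohort,
    generate_follower,
    generate_questionnaires,
)


class TestScoreSpec:
    def test_alternation_enforced_without_rest(self):
        with pytest.raises(ValueError, match="alternate"):
            ScoreSpec([StrokeEvent("down", 300, 0.5), StrokeEvent("down", 300, 0.5)])

    def test_same_direction_allowed_after_rest(self):
        ScoreSpec(
            [
                StrokeEvent("down", 300, 0.5, rest_after=0.5),
                StrokeEvent("down", 300, 0.5),
            ]
        )

    @pytest.mark.parametrize("bad", [dict(length=-1), dict(duration=0)])
    def test_positive_lengths_and_durations(self, bad):
        kw = dict(direction="down", length=300.0, duration=0.5)
        kw.update(bad)
        with pytest.raises(ValueError):
            ScoreSpec([StrokeEvent(**kw)])


class TestAvatar:
    def test_empty_score_raises(self):
        with pytest.raises(ValueError, match="empty score"):
            generate_avatar(ScoreSpec([]), seed=0)

    def test_ten_monotone_segments(self, simple_score, avatar_trace):
        kin = bow_contact_kinematics(avatar_trace)
        moving = np.abs(np.gradient(kin.dist_frog)) > 0.2
        d = np.sign(np.diff(kin.dist_frog))
        d[~moving[:-1]] = 0
        d = d[d != 0]
        n_segments = 1 + int(np.sum(np.diff(d) != 0))
        assert n_segments == 10

    def test_min_jerk_peak_speed(self, avatar_trace):
        # closed form peak of the minimum-jerk profile: 1.875 L / T
        kin = bow_contact_kinematics(avatar_trace)
        v = np.gradient(kin.dist_frog, kin.time)
        assert np.abs(v).max() == pytest.approx(1.875 * 300.0 / 0.5, rel=0.01)

    def test_determinism(self, simple_score):
        t1, a1 = generate_avatar(simple_score, seed=42)
        t2, a2 = generate_avatar(simple_score, seed=42)
        assert np.array_equal(a1.samples, a2.samples)
        for m in t1.markers:
            assert np.array_equal(t1.markers[m], t2.markers[m])

    def test_audio_envelope_tracks_dynamic(self):
        score = ScoreSpec(
            [
                StrokeEvent("down", 300, 0.5, dynamic=1.0, rest_after=0.5),
                StrokeEvent("up", 300, 0.5, dynamic=0.25),
            ]
        )
        trace, audio = generate_avatar(score, seed=0)
        fa = audio.rate

        def rms(t0, t1):
            seg = audio.samples[int(t0 * fa) : int(t1 * fa)]
            return np.sqrt(np.mean(seg**2))

        # lead-in is 0.3 s; strokes at [0.3, 0.8] and [1.3, 1.8]
        assert rms(0.45, 0.65) == pytest.approx(1.0 / np.sqrt(2), rel=0.02)
        assert rms(1.45, 1.65) == pytest.approx(0.25 / np.sqrt(2), rel=0.02)
        assert rms(0.95, 1.15) < 1e-6  # rest

    def test_motion_and_audio_share_time_zero(self, avatar_trace, avatar_audio):
        assert avatar_trace.time[0] == 0.0
        assert avatar_audio.duration >= avatar_trace.duration


class TestFollower:
    def test_neutral_params_identity(self, avatar_trace):
        f = generate_follower(avatar_trace, FidelityParams())
        for m in avatar_trace.markers:
            assert np.array_equal(f.markers[m], avatar_trace.markers[m])

    def test_neutral_gives_zero_pd_end_to_end(self, avatar_trace, avatar_audio):
        f = generate_follower(avatar_trace, FidelityParams())
        ms = pipeline.extract_stroke_metrics(avatar_trace, f, avatar_audio)
        assert len(ms) > 0
        assert all(m.pd < 1e-12 for m in ms)
        assert all(m.dsi == 0.0 for m in ms)

    def test_pd_monotone_in_spatial_noise(self, avatar_trace, avatar_audio):
        means = []
        for sd in (0.0, 2.0, 6.0):
            pds = []
            for seed in range(5):
                f = generate_follower(
                    avatar_trace, FidelityParams(spatial_noise_sd=sd, seed=seed)
                )
                pds += [m.pd for m in pipeline.extract_stroke_metrics(avatar_trace, f, avatar_audio)]
            assert len(pds) >= 50
            means.append(np.mean(pds))
        assert means[0] < means[1] < means[2]

    def test_tremor_lowers_follower_sparc(self, avatar_trace, avatar_audio):
        f = generate_follower(
            avatar_trace, FidelityParams(tremor_amp=3.0, tremor_freq=8.0, seed=1)
        )
        ms = pipeline.extract_stroke_metrics(avatar_trace, f, avatar_audio)
        assert len(ms) > 0
        assert all(m.si_participant < m.si_avatar for m in ms)
        assert np.mean([m.dsi for m in ms]) < -0.05

    def test_sparc_monotone_in_tremor(self, avatar_trace, avatar_audio):
        means = []
        for amp in (0.0, 1.5, 4.0):
            dsis = []
            for seed in range(3):
                f = generate_follower(
                    avatar_trace, FidelityParams(tremor_amp=amp, seed=seed)
                )
                dsis += [
                    m.dsi for m in pipeline.extract_stroke_metrics(avatar_trace, f, avatar_audio)
                ]
            means.append(np.mean(dsis))
        assert means[0] > means[1] > means[2]

    def test_lag_exceeding_duration_raises(self, avatar_trace):
        with pytest.raises(ValueError, match="lag"):
            generate_follower(avatar_trace, FidelityParams(tracking_lag=1e4))

    def test_tremor_above_nyquist_raises(self, avatar_trace):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_follower(
                avatar_trace, FidelityParams(tremor_amp=1.0, tremor_freq=80.0)
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            FidelityParams(spatial_noise_sd=-1.0)

    def test_determinism(self, avatar_trace):
        p = FidelityParams(spatial_noise_sd=3.0, tremor_amp=2.0, seed=7)
        f1 = generate_follower(avatar_trace, p)
        f2 = generate_follower(avatar_trace, p)
        for m in f1.markers:
            assert np.array_equal(f1.markers[m], f2.markers[m])


class TestCohort:
    def test_default_design_counts(self):
        design = default_design(seed=0)
        bundle = generate_cohort(design)
        assert len(bundle.cells) == 11 * 2 * 4 == 88
        assert design.n_cells == 88
        assert len(bundle.profiles) == 11

    def test_cell_count_conservation(self):
        design = CohortDesign(n_participants=5, n_trials=3, seed=1)
        assert len(generate_cohort(design).cells) == 5 * 2 * 3

    def test_null_effects_recorded_as_zero_deltas(self):
        design = CohortDesign(
            seed=0,
            condition_effects={"2D": ConditionEffect(), "3D": ConditionEffect()},
        )
        ledger = generate_cohort(design).ledger
        assert (ledger["delta_noise_scale"] == 0).all()
        assert (ledger["delta_tremor_scale"] == 0).all()
        assert (ledger["delta_presence"] == 0).all()

    def test_ledger_determinism(self):
        l1 = generate_cohort(default_design(seed=5)).ledger
        l2 = generate_cohort(default_design(seed=5)).ledger
        pd.testing.assert_frame_equal(l1, l2)

    def test_condition_effects_applied_multiplicatively(self):
        ledger = generate_cohort(default_design(seed=2)).ledger
        wide = ledger.pivot_table(
            index=["participant", "trial"], columns="condition", values="spatial_noise_sd"
        )
        assert np.allclose(wide["2D"] / wide["3D"], 1.5)

    def test_piece_groups_form_four_cells(self):
        ledger = generate_cohort(default_design(seed=0)).ledger
        groups = set(map(tuple, ledger[["piece", "violin_section"]].drop_duplicates().itertuples(index=False)))
        assert len(groups) == 4

    def test_profile_ranges(self):
        for p in generate_cohort(default_design(seed=3)).profiles:
            assert 18 <= p.age <= 25
            assert p.years_played >= 12
            assert p.violin_section in (1, 2)


class TestQuestionnaires:
    def test_eight_administrations_per_participant(self):
        q = generate_questionnaires(default_design(seed=0))
        counts = q.groupby("participant").size()
        assert (counts == 8).all()
        assert len(q) == 88

    def test_items_within_likert_ranges(self):
        q = generate_questionnaires(default_design(seed=1))
        wpq = q[[c for c in q.columns if c.startswith("WPQ_")]]
        mpq = q[[c for c in q.columns if c.startswith("MPQ")]]
        assert wpq.min().min() >= 1 and wpq.max().max() <= 7
        assert mpq.min().min() >= 1 and mpq.max().max() <= 5
        assert q["difficulty"].between(0, 100).all()

    def test_zero_shift_gives_no_condition_difference(self):
        design = CohortDesign(
            n_participants=150,
            n_trials=2,
            seed=4,
            condition_effects={"2D": ConditionEffect(), "3D": ConditionEffect()},
        )
        q = generate_questionnaires(design)
        cols = [c for c in q.columns if c.startswith("WPQ_")]
        means = q.groupby("condition")[cols].mean().mean(axis=1)
        assert abs(means["2D"] - means["3D"]) < 0.08

    def test_condition_shift_moves_presence(self):
        q = generate_questionnaires(default_design(seed=6))
        cols = [c for c in q.columns if c.startswith("MPQS_")]
        means = q.groupby("condition")[cols].mean().mean(axis=1)
        assert means["3D"] - means["2D"] > 0.3  # default shift is 0.6

    @pytest.mark.parametrize("target", [0.7, 0.85])
    def test_alpha_recovery(self, target):
        # ~500 administrations; expected Cronbach alpha near the target
        design = CohortDesign(
            n_participants=125,
            n_trials=2,
            seed=7,
            condition_effects={"2D": ConditionEffect(), "3D": ConditionEffect()},
        )
        q = generate_questionnaires(design, n_items={"WPQ": 5}, reliability_target=target)
        items = q[[f"WPQ_{i}" for i in range(1, 6)]].to_numpy()
        assert cronbach_alpha(items) == pytest.approx(target, abs=0.05)

    def test_reliability_target_validated(self):
        with pytest.raises(ValueError, match="reliability"):
            generate_questionnaires(default_design(seed=0), reliability_target=1.5)

    def test_min_items_validated(self):
        with pytest.raises(ValueError, match="2 items"):
            generate_questionnaires(default_design(seed=0), n_items={"WPQ": 1})

    def test_determinism(self):
        q1 = generate_questionnaires(default_design(seed=9))
        q2 = generate_questionnaires(default_design(seed=9))
        pd.testing.assert_frame_equal(q1, q2)
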