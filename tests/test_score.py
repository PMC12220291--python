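import numpy as np
import pytest

from singscore import (
    InputError,
    ScoreConfig,
    ScoringError,
    Segment,
    SynthConfig,
    contour_error,
    derive_segments,
    parsons_code,
    pitch_error,
    remove_outliers,
    render_contour,
    rhythm_error,
    score_contour,
)

from test_template import make_template


class TestRemoveOutliers:
    def test_identical_sequences_keep_everything(self):
        x = np.array([60.0, 62.0, 64.0, 60.0] * 50)
        mask, shifted = remove_outliers(x, x)
        assert mask.all()
        np.testing.assert_allclose(shifted, x)

    def test_single_octave_error_frame_is_masked(self):
        template = np.full(201, 60.0)
        contour = template.copy()
        contour[100] += 12.0  # one octave-error frame among 200 accurate ones
        mask, _ = remove_outliers(contour, template)
        assert not mask[100]
        assert mask.sum() == 200

    def test_final_shift_zeroes_median_masked_difference(self):
        rng = np.random.default_rng(3)
        template = np.repeat([60.0, 62.0, 64.0], 40)
        contour = template + rng.normal(0.7, 0.3, size=template.size)
        mask, shifted = remove_outliers(contour, template)
        assert np.median((contour - shifted)[mask]) == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            remove_outliers(np.zeros(3), np.zeros(4))


class TestSegments:
    def test_first_bar_gives_four_segments(self):
        t = np.array([0.0, 0, 2, 2, 4, 4, 0, 0])
        segments, dropped = derive_segments(t, t)
        assert dropped == 0
        assert [s.template_pitch for s in segments] == [0.0, 2.0, 4.0, 0.0]
        assert [(s.start, s.end) for s in segments] == [(0, 2), (2, 4), (4, 6), (6, 8)]

    def test_constant_template_is_one_segment(self):
        t = np.full(10, 5.0)
        segments, _ = derive_segments(t, t)
        assert len(segments) == 1

    def test_segment_count_bounded_by_note_count(self, song):
        from singscore import expand_template

        curve = expand_template(song, steps_per_eighth=4)
        segments, _ = derive_segments(curve.values, curve.values, note_ids=curve.note_ids)
        assert len(segments) <= len(song)
        unmerged, _ = derive_segments(
            curve.values, curve.values, note_ids=curve.note_ids, merge_equal_pitch=False
        )
        assert len(unmerged) == len(song)

    def test_fully_masked_segment_dropped_and_counted(self):
        t = np.repeat([0.0, 2.0, 4.0], 4)
        mask = np.ones(12, bool)
        mask[4:8] = False
        segments, dropped = derive_segments(t, t, mask=mask)
        assert dropped == 1
        assert [s.template_pitch for s in segments] == [0.0, 4.0]

    def test_segment_medians_use_retained_frames_only(self):
        t = np.zeros(6)
        c = np.array([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        mask = np.array([True, True, True, False, False, False])
        segments, _ = derive_segments(t, c, mask=mask)
        assert segments[0].median_pitch == 1.0


def toy_segments(devs, template_pitch=60.0):
    devs = np.asarray(devs, float)
    centred = devs - devs.mean()
    return [
        Segment(start=i, end=i + 1, template_pitch=template_pitch,
                median_pitch=template_pitch + d, n_voiced=1)
        for i, d in enumerate(centred)
    ]


class TestPitchError:
    def test_one_note_off_in_eight_after_mean_reshift(self):
        """One +1 st note among eight: residuals 7/8 and 7 x 1/8 -> 14/64."""
        segments = toy_segments([1.0] + [0.0] * 7)
        assert pitch_error(segments) == pytest.approx(14 / 64)

    def test_exact_segments_score_zero(self):
        assert pitch_error(toy_segments([0.0] * 5)) == 0.0

    def test_no_segments_raises(self):
        with pytest.raises(ScoringError):
            pitch_error([])


class TestParsonsCode:
    def test_template_first_phrase_directions(self):
        assert parsons_code([0, 2, 4, 0]).tolist() == [1, 1, -1]

    def test_constant_is_all_repeats(self):
        assert parsons_code([5, 5, 5]).tolist() == [0, 0]

    def test_inverted_melody_negates_codes(self):
        v = np.array([0.0, 2, 1, 3, 3])
        np.testing.assert_array_equal(parsons_code(-v), -parsons_code(v))

    def test_deadband_treats_small_steps_as_repeats(self):
        assert parsons_code([60.0, 60.3, 61.0], deadband=0.5).tolist() == [0, 1]

    def test_needs_two_values(self):
        with pytest.raises(InputError):
            parsons_code([60.0])


class TestContourError:
    def test_identical_codes_score_zero(self):
        assert contour_error([1, 0, -1], [1, 0, -1]) == 0.0

    def test_single_inversion_contributes_two(self):
        assert contour_error([-1], [1]) == 2.0

    def test_fully_inverted_template(self):
        codes = parsons_code([0, 2, 4, 0, 2])
        c = np.count_nonzero(codes)
        assert contour_error(-codes, codes) == 2.0 * c

    def test_even_under_joint_negation(self, rng):
        s = rng.integers(-1, 2, size=30)
        t = rng.integers(-1, 2, size=30)
        assert contour_error(s, t) == contour_error(-s, -t)

    def test_length_mismatch_raises(self):
        with pytest.raises(ScoringError):
            contour_error([1], [1, 0])


class TestRhythmError:
    def test_constant_shift_is_zero(self):
        assert rhythm_error(np.full(50, 0.7), eighth_len=8.0) == 0.0

    def test_single_delayed_note_raises_error_above_zero(self):
        shifts = np.concatenate([np.zeros(20), np.full(10, 0.5), np.zeros(20)])
        assert rhythm_error(shifts, eighth_len=4.0) > 0.0

    def test_unit_conversion(self):
        # shift ramps 0 -> 1 eighth over 10 frames of 1/5 eighth each: slope 0.5
        shifts = np.linspace(0.0, 1.0, 11)
        assert rhythm_error(shifts, eighth_len=5.0) == pytest.approx(0.5)

    def test_too_short_series_raises(self):
        with pytest.raises(ScoringError):
            rhythm_error(np.array([0.0]), 1.0)


class TestScoreContour:
    def test_perfect_rendition_scores_zero(self, song):
        contour, _ = render_contour(song, SynthConfig(seed=0))
        scores = score_contour(contour, song)
        assert scores.pitch_error == pytest.approx(0.0, abs=1e-12)
        assert scores.melody_error == 0.0
        assert scores.rhythm_error == pytest.approx(0.0, abs=1e-12)

    def test_transposed_rendition_scores_zero(self, song):
        contour, _ = render_contour(song, SynthConfig(seed=0, transpose_semitones=3.0))
        scores = score_contour(contour, song)
        assert scores.pitch_error == pytest.approx(0.0, abs=1e-12)

    def test_pitch_error_tracks_ground_truth_within_20pct(self, verse):
        est, truth = [], []
        for seed in range(20):
            cfg = SynthConfig(seed=seed, note_offset_sd=1.0)
            contour, gt = render_contour(verse, cfg)
            est.append(score_contour(contour, verse).pitch_error)
            truth.append(gt.true_mean_abs_pitch_dev)
        assert np.mean(est) == pytest.approx(np.mean(truth), rel=0.2)

    def test_monotone_in_injected_severity(self, verse):
        """Mean scores rise with injected pitch scatter and timing jitter."""
        pitch_means, rhythm_means = [], []
        for level in range(4):
            ps, rs = [], []
            for seed in range(8):
                cfg = SynthConfig(
                    seed=seed,
                    note_offset_sd=0.5 * level,
                    timing_jitter_sd_eighths=0.12 * level,
                )
                contour, _ = render_contour(verse, cfg)
                s = score_contour(contour, verse)
                ps.append(s.pitch_error)
                rs.append(s.rhythm_error)
            pitch_means.append(np.mean(ps))
            rhythm_means.append(np.mean(rs))
        assert np.all(np.diff(pitch_means) > 0)
        assert np.all(np.diff(rhythm_means) > 0)

    def test_gap_in_contour_rejected(self, verse):
        with pytest.raises(InputError):
            score_contour(np.array([60.0, np.nan, 62.0]), verse)

    def test_config_roundtrips_to_dict(self):
        cfg = ScoreConfig()
        d = cfg.as_dict()
        assert d["outlier_sd"] == 2.5 and d["yin_threshold"] == 0.1
        assert ScoreConfig(**d) == cfg
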