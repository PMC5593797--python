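import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sine_recording
from cryseg.evaluation import (
    frame_confusion,
    overall_accuracy,
    rates,
    track_to_frame_labels,
)
from cryseg.features import F0Track
from cryseg.postprocess import (
    RelabelRules,
    ThresholdSet,
    build_intervals,
    classify_intervals,
    combine_indices,
    compute_thresholds,
    finalize_labels,
    mark_intensity_minima,
    mark_transitions,
    merge_with_initial,
    refine,
    voicing_index,
)
from cryseg.preprocess import frame_signal
from cryseg.synthetic import Event, SceneSpec, render_scene

# ---------------------------------------------------------------------------
# Worked indexing example: a 16-frame stretch whose voicing column is
# [1]*5 + [0]*4 + [1]*4 + [0]*3 with intensity minima at frames 1, 7, 11, 13.
VOICING_16 = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0])
MINIMA_FRAMES = [1, 7, 11, 13]
COMBINED_16 = np.array([2, 1, 1, 1, 2, 0, 2, 0, 2, 1, 2, 1, 2, 0, 0, 2])
INTERVALS_6 = [(1, 5), (6, 7), (8, 9), (10, 11), (12, 13), (14, 16)]
NEW_INDEX_6 = [0, 0, 1, 1, 0, 1]
INITIAL_16 = np.array(["BKG"] * 5 + ["EXP"] * 4 + ["INS"] * 4 + ["NOR"] * 3)
COMPOSITE_16 = [
    "BKG0", "BKG0", "BKG0", "BKG0", "BKG0",
    "EXP0", "EXP0", "EXP1", "EXP1",
    "INS1", "INS1", "INS0", "INS0",
    "NOR1", "NOR1", "NOR1",
]


def minima_marks_16():
    marks = np.zeros(16, dtype=bool)
    marks[[f - 1 for f in MINIMA_FRAMES]] = True
    return marks


def threshold_oracle(int_sil, int_sig, zcr_sil):
    """Literal evaluation of the printed threshold equations."""
    zc_bkg = np.mean(zcr_sil) + 2 * np.std(zcr_sil)
    imean = np.mean(int_sil)
    imax = np.max(int_sig)
    i1 = 0.03 * (imax - imean) + imean
    i2 = 4 * imean
    itl = min(i1, i2)
    return zc_bkg, imean, imax, i1, i2, itl, 5 * itl


class TestThresholds:
    def test_worked_numbers(self):
        # silence at a constant 10 dB, signal peak 110 dB
        n_sil = 27  # 250 ms at the 9 ms hop: round(0.250/0.009) == 28? -> computed below
        intensity = np.concatenate([np.full(30, 10.0), [110.0], np.full(30, 10.0)])
        labels = np.array(["BKG"] * 30 + ["EXP"] * 31)
        zcr = np.full(61, 3.0)
        th = compute_thresholds(intensity, zcr, labels, hop_s=0.009,
                                linear_energy=False)
        assert th.imean == pytest.approx(10.0)
        assert th.imax == pytest.approx(110.0)
        assert th.i1 == pytest.approx(13.0)
        assert th.i2 == pytest.approx(40.0)
        assert th.itl == pytest.approx(13.0)
        assert th.int_bkg == pytest.approx(65.0)
        assert th.zc_bkg == pytest.approx(3.0)  # constant ZCR -> std 0 -> mean

    def test_matches_literal_formulas_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(40, 200))
            intensity = rng.uniform(-60, 20, n)
            zcr = rng.uniform(0, 200, n)
            labels = np.array(["BKG"] * n)
            th = compute_thresholds(intensity, zcr, labels, hop_s=0.009,
                                    linear_energy=False)
            n_sil = min(n, max(1, round(0.250 / 0.009)))
            zc, imean, imax, i1, i2, itl, int_bkg = threshold_oracle(
                intensity[:n_sil], intensity, zcr[:n_sil]
            )
            assert th.zc_bkg == pytest.approx(zc, rel=1e-12)
            assert th.itl == pytest.approx(itl, rel=1e-12)
            assert th.int_bkg == pytest.approx(int_bkg, rel=1e-12)

    def test_all_background_signal(self):
        intensity = np.full(100, 12.0)
        intensity[50] = 12.5  # Imax barely above Imean
        labels = np.array(["BKG"] * 100)
        th = compute_thresholds(intensity, np.full(100, 5.0), labels,
                                hop_s=0.009, linear_energy=False)
        assert th.itl == th.i1  # I1 < I2 when Imax is close to Imean
        assert th.int_bkg == pytest.approx(5 * th.i1)

    def test_fallback_quietest_window_without_bkg(self):
        intensity = np.concatenate([np.full(50, 0.0), np.full(30, -40.0),
                                    np.full(50, 0.0)])
        labels = np.array(["EXP"] * 130)
        th = compute_thresholds(intensity, np.zeros(130), labels, hop_s=0.009,
                                linear_energy=False)
        assert set(th.source).issubset(set(range(50, 80)))

    def test_short_signal_uses_all_frames_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            th = compute_thresholds(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                                    np.array(["BKG", "BKG"]), hop_s=0.009,
                                    linear_energy=False)
        assert th.source.size == 2

    def test_linear_energy_mode_thresholds_in_db(self):
        intensity = np.concatenate([np.full(30, -40.0), np.full(30, 0.0)])
        labels = np.array(["BKG"] * 30 + ["EXP"] * 30)
        th = compute_thresholds(intensity, np.zeros(60), labels, hop_s=0.009,
                                linear_energy=True)
        # threshold should separate -40 dB silence from 0 dB activity
        assert -40.0 < th.int_bkg < 0.0


class TestIndexing:
    def test_voicing_index_from_f0_presence(self):
        f0 = F0Track(np.where(VOICING_16 == 1, 300.0, np.nan))
        np.testing.assert_array_equal(voicing_index(f0), VOICING_16)

    def test_voicing_index_empty_rejected(self):
        with pytest.raises(ValueError):
            voicing_index(F0Track(np.array([])))

    def test_transitions_sit_on_last_frame_of_runs(self):
        marks = mark_transitions(VOICING_16)
        assert list(np.flatnonzero(marks) + 1) == [5, 9, 13]

    def test_constant_voicing_has_no_transitions(self):
        assert not mark_transitions(np.ones(10, dtype=int)).any()

    def test_alternating_voicing_marks_every_boundary(self):
        marks = mark_transitions(np.array([1, 0, 1, 0]))
        assert list(np.flatnonzero(marks) + 1) == [1, 2, 3]

    def test_minima_strictly_increasing_marks_first_frame(self):
        marks = mark_intensity_minima(np.arange(10, dtype=float))
        assert list(np.flatnonzero(marks) + 1) == [1]

    def test_minima_v_shape(self):
        marks = mark_intensity_minima(np.array([5.0, 3.0, 5.0]))
        assert list(np.flatnonzero(marks) + 1) == [2]

    def test_minima_constructed_contour(self):
        contour = np.array([0, 5, 6, 7, 8, 6, 2, 4, 9, 8, 3, 5, 1, 2, 3, 4],
                           dtype=float)
        marks = mark_intensity_minima(contour)
        assert list(np.flatnonzero(marks) + 1) == MINIMA_FRAMES

    def test_combination_reproduces_worked_column(self):
        combined = combine_indices(
            VOICING_16, mark_transitions(VOICING_16), minima_marks_16()
        )
        np.testing.assert_array_equal(combined, COMBINED_16)

    def test_no_marks_keeps_voicing_plus_final_boundary(self):
        v = np.array([1, 1, 0, 0, 1])
        combined = combine_indices(v, np.zeros(5, bool), np.zeros(5, bool))
        np.testing.assert_array_equal(combined, [1, 1, 0, 0, 2])

    def test_all_marked_all_two(self):
        combined = combine_indices(np.zeros(4, int), np.ones(4, bool),
                                   np.zeros(4, bool))
        np.testing.assert_array_equal(combined, 2)


class TestIntervals:
    def test_worked_interval_spans(self):
        assert build_intervals(COMBINED_16) == INTERVALS_6

    def test_all_marked_gives_singletons(self):
        assert build_intervals(np.full(5, 2)) == [(i, i) for i in range(1, 6)]

    def test_single_trailing_boundary_spans_everything(self):
        assert build_intervals(np.array([1, 0, 1, 2])) == [(1, 4)]

    def test_final_frame_must_be_boundary(self):
        with pytest.raises(ValueError):
            build_intervals(np.array([2, 1, 0]))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=40))
    def test_intervals_partition_frames(self, combined):
        combined = np.array(combined + [2])
        intervals = build_intervals(combined)
        # exact partition of 1..n: contiguous, ordered, covering
        assert intervals[0][0] == 1
        assert intervals[-1][1] == combined.size
        for (_, e1), (s2, _) in zip(intervals, intervals[1:]):
            assert s2 == e1 + 1
        for s, e in intervals:
            assert s <= e

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from([0, 1]), min_size=2, max_size=40))
    def test_transition_marks_count_voicing_runs(self, voicing):
        voicing = np.array(voicing)
        marks = mark_transitions(voicing)
        n_runs = 1 + int(np.sum(voicing[1:] != voicing[:-1]))
        assert int(marks.sum()) == n_runs - 1

    def test_activity_by_intensity_or_zcr(self):
        th = ThresholdSet(zc_bkg=10.0, int_bkg=50.0, imean=0, imax=0,
                          i1=0, i2=0, itl=0)
        intensity = np.array([80.0, 80.0, 10.0, 10.0, 10.0, 10.0])
        zcr = np.array([0.0, 0.0, 0.0, 0.0, 30.0, 30.0])
        idx = classify_intervals([(1, 2), (3, 4), (5, 6)], intensity, zcr, th)
        assert idx == [1, 0, 1]  # loud; neither; high-ZCR

    def test_worked_composite_column(self):
        composite = merge_with_initial(INITIAL_16, INTERVALS_6, NEW_INDEX_6)
        assert list(composite) == COMPOSITE_16

    def test_uniform_inputs_uniform_composite(self):
        composite = merge_with_initial(np.array(["EXP"] * 4), [(1, 4)], [1])
        assert list(composite) == ["EXP1"] * 4

    def test_gap_in_intervals_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            merge_with_initial(INITIAL_16, [(1, 5)], [0])


class TestFinalize:
    def _track_labels(self, track, n, frame_len_s=0.030, hop_s=0.009):
        return track_to_frame_labels(track, n, frame_len_s, hop_s, collapse=False)

    def test_all_inactive_becomes_single_background(self):
        composite = np.array(["BKG0"] * 10)
        f0 = F0Track(np.full(10, np.nan))
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        track = finalize_labels(composite, np.zeros(10), f0, th)
        assert len(track) == 1
        assert track.segments[0].label == "BKG"
        assert track.segments[0].start_s == 0.0
        assert track.segments[0].end_s == pytest.approx(9 * 0.009 + 0.030)

    @pytest.mark.parametrize(
        "center,expected",
        [(400.0, "EXP"), (150.0, "INS"), (1400.0, "NOR")],
    )
    def test_active_noise_run_relabeled_by_f0_band(self, center, expected):
        composite = np.array(["NOR1"] * 6)
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        f0 = F0Track(center + np.array([-5.0, -3.0, 0.0, 0.0, 3.0, 5.0]))
        track = finalize_labels(composite, np.zeros(6), f0, th)
        assert track.segments[0].label == expected

    def test_constant_f0_run_is_beep_not_cry(self):
        # a machine beep holds its fundamental exactly; phonation never does
        composite = np.array(["NOR1"] * 6)
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        track = finalize_labels(composite, np.zeros(6), F0Track(np.full(6, 400.0)), th)
        assert track.segments[0].label == "NOR"

    def test_sparsely_voiced_run_keeps_class(self):
        # two spuriously voiced frames out of ten are not a fundamental
        composite = np.array(["NOR1"] * 10)
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        f0 = np.full(10, np.nan)
        f0[[3, 7]] = [350.0, 450.0]
        track = finalize_labels(composite, np.zeros(10), F0Track(f0), th)
        assert track.segments[0].label == "NOR"

    def test_unvoiced_active_run_keeps_class_with_warning(self):
        composite = np.array(["NOR1"] * 5)
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        with pytest.warns(UserWarning, match="no voiced frame"):
            track = finalize_labels(composite, np.zeros(5),
                                    F0Track(np.full(5, np.nan)), th)
        assert track.segments[0].label == "NOR"

    def test_active_exp_run_boundaries_tightened(self):
        # EXP0 margins around an EXP1 core: final EXP must hug the core
        composite = np.array(["EXP0"] * 4 + ["EXP1"] * 6 + ["EXP0"] * 4)
        f0 = F0Track(np.concatenate([np.full(4, np.nan), np.full(6, 400.0),
                                     np.full(4, np.nan)]))
        th = ThresholdSet(0, 0, 0, 0, 0, 0, 0)
        track = finalize_labels(composite, np.zeros(14), f0, th)
        exp = [s for s in track if s.label == "EXP"]
        assert len(exp) == 1
        half = (0.030 - 0.009) / 2
        # EXP pulled in to the active core, within half a frame of its edges
        assert exp[0].start_s == pytest.approx(4 * 0.009 + half)
        assert exp[0].end_s == pytest.approx(10 * 0.009 + half)


class TestRefine:
    def test_output_partitions_recording(self, cry_scene):
        rec, truth = cry_scene
        fm = frame_signal(rec)
        ref = track_to_frame_labels(truth, fm.n_frames, fm.frame_len_s, fm.hop_s)
        track = refine(ref, rec)
        for a, b in zip(track.segments, track.segments[1:]):
            assert b.start_s == pytest.approx(a.end_s, abs=1e-9)
        assert track.segments[0].start_s == 0.0

    def test_clean_scene_nearly_unchanged(self, cry_scene):
        rec, truth = cry_scene
        fm = frame_signal(rec)
        ref = track_to_frame_labels(truth, fm.n_frames, fm.frame_len_s, fm.hop_s)
        track = refine(ref, rec)
        hyp = track_to_frame_labels(track, fm.n_frames, fm.frame_len_s,
                                    fm.hop_s, collapse=False)
        assert overall_accuracy(ref, hyp) >= 95.0

    def test_pure_noise_recording_yields_no_cry_segments(self, rng):
        from cryseg.io_formats import AudioRecording

        rec = AudioRecording(0.003 * rng.standard_normal(32000), 16000)
        fm = frame_signal(rec)
        track = refine(np.array(["BKG"] * fm.n_frames), rec)
        assert {s.label for s in track} <= {"BKG", "NOR"}

    def test_reduces_false_positive_expiration(self, cry_scene, rng):
        rec, truth = cry_scene
        fm = frame_signal(rec)
        ref = track_to_frame_labels(truth, fm.n_frames, fm.frame_len_s, fm.hop_s)
        corrupted = ref.copy()
        bkg = np.flatnonzero(ref == "BKG")
        flip = rng.choice(bkg, size=len(bkg) // 3, replace=False)
        corrupted[flip] = "EXP"
        fpr_before = rates(frame_confusion(ref, corrupted, "EXP"))["FPR"]
        track = refine(corrupted, rec)
        hyp = track_to_frame_labels(track, fm.n_frames, fm.frame_len_s,
                                    fm.hop_s, collapse=False)
        fpr_after = rates(frame_confusion(ref, hyp, "EXP"))["FPR"]
        assert fpr_after < fpr_before

    def test_label_count_mismatch_rejected(self, cry_scene):
        rec, _ = cry_scene
        with pytest.raises(ValueError):
            refine(np.array(["BKG"] * 10), rec)
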