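"""Trial CO2 changes, quality grading, blocks and training segments."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhcvr.endtidal import PeakSet
from bhcvr.physio import TaskTiming, Trace
from bhcvr.quality import (
    HIGH,
    LOW,
    SKIPPED,
    TrialChange,
    build_blocks,
    classify_trials,
    quality_threshold,
    segment_for_training,
    trial_deltas,
)


def _timing_one_hold(hs=12.0, he=28.0):
    return TaskTiming(trials=[(2.0, hs, he, he + 15.0)])


class TestTrialDeltas:
    def test_flanking_peaks_subtraction(self):
        co2 = Trace(np.zeros(400), fs=10, units="mmHg")
        co2.samples[100], co2.samples[300] = 38.0, 46.0
        peaks = PeakSet([100, 300], "endtidal_max")
        (change,) = trial_deltas(co2, peaks, _timing_one_hold())
        assert change.delta == pytest.approx(8.0)

    def test_missing_post_hold_peak_marks_delta_missing(self):
        co2 = Trace(np.zeros(400), fs=10, units="mmHg")
        co2.samples[100] = 38.0
        peaks = PeakSet([100], "endtidal_max")
        (change,) = trial_deltas(co2, peaks, _timing_one_hold())
        assert change.missing
        labels = classify_trials([change], threshold=3.0)
        assert labels == [LOW]

    def test_skipped_trial_has_no_delta(self):
        timing = TaskTiming(trials=[(2.0, 12.0, 28.0, 43.0)], skipped=[True])
        co2 = Trace(np.zeros(500), fs=10, units="mmHg")
        co2.samples[[100, 300]] = [38.0, 46.0]
        (change,) = trial_deltas(co2, PeakSet([100, 300], "endtidal_max"), timing)
        assert change.missing


class TestQualityThreshold:
    def test_published_test_dataset_statistics(self):
        # two symmetric deltas realize mean 6.73 and sample SD 3.13 exactly
        d = 3.13 / np.sqrt(2)
        deltas = [6.73 - d, 6.73 + d]
        assert np.mean(deltas) == pytest.approx(6.73)
        assert np.std(deltas, ddof=1) == pytest.approx(3.13)
        assert quality_threshold(deltas) == pytest.approx(3.60, abs=1e-12)

    def test_hand_computed_sample_sd(self):
        assert quality_threshold([8, 7, 2, 9]) == pytest.approx(6.5 - 3.1091, abs=1e-3)

    def test_single_delta_has_zero_sd(self):
        assert quality_threshold([5.0]) == pytest.approx(5.0)

    def test_negative_deltas_excluded_from_the_pool(self):
        assert quality_threshold([5.0, -3.0, None]) == pytest.approx(5.0)

    def test_no_positive_deltas_is_an_error(self):
        with pytest.raises(ValueError, match="no usable"):
            quality_threshold([-1.0, None])

    def test_population_sd_option(self):
        # n-denominator variant changes the toy threshold
        assert quality_threshold([8, 7, 2, 9], ddof=0) == pytest.approx(6.5 - 2.6926, abs=1e-3)


class TestClassify:
    def _changes(self, deltas):
        return [TrialChange(i, None, None, d) for i, d in enumerate(deltas)]

    def test_threshold_comparison(self):
        labels = classify_trials(self._changes([8, 7, 2, 9]), quality_threshold([8, 7, 2, 9]))
        assert labels == [HIGH, HIGH, LOW, HIGH]

    def test_all_equal_deltas_all_high(self):
        deltas = [6.0] * 5
        labels = classify_trials(self._changes(deltas), quality_threshold(deltas))
        assert labels == [HIGH] * 5

    def test_skipped_label_from_timing(self):
        timing = TaskTiming(
            trials=[(0.0, 5.0, 15.0, 30.0), (31.0, 40.0, 50.0, 65.0)],
            skipped=[False, True],
        )
        changes = [TrialChange(0, 38.0, 45.0, 7.0), TrialChange(1, None, None, None)]
        assert classify_trials(changes, 3.0, timing) == [HIGH, SKIPPED]

    @given(st.lists(st.floats(0.5, 20), min_size=2, max_size=10), st.integers(0, 9))
    @settings(max_examples=50, deadline=None)
    def test_raising_one_delta_never_demotes_others(self, deltas, which):
        which = which % len(deltas)
        thr = quality_threshold(deltas)
        before = classify_trials(self._changes(deltas), thr)
        raised = list(deltas)
        raised[which] += 5.0
        after = classify_trials(self._changes(raised), thr)
        for i in range(len(deltas)):
            if i != which and before[i] == HIGH:
                assert after[i] == HIGH


class TestBlocks:
    def _timing(self, n=3, skipped=None):
        trials = []
        t = 5.0
        for _ in range(n):
            trials.append((t, t + 20.0, t + 36.0, t + 55.0))
            t += 55.0
        return TaskTiming(trials=trials, skipped=skipped or [False] * n)

    def test_boundary_at_halfway_point(self):
        timing = TaskTiming(
            trials=[(0.0, 10.0, 30.0, 45.0), (50.0, 70.0, 90.0, 110.0)]
        )
        grid = Trace(np.zeros(1200), fs=10)
        blocks = build_blocks(timing, [HIGH, HIGH], grid)
        assert blocks[0].end_sample == 500  # (30 + 70) / 2 = 50 s
        assert blocks[1].start_sample == 500

    def test_blocks_tile_the_trace(self):
        grid = Trace(np.zeros(1800), fs=10)
        timing = self._timing(3)
        blocks = build_blocks(timing, [HIGH] * 3, grid)
        assert blocks[0].start_sample == 0
        assert blocks[-1].end_sample == len(grid)
        for a, b in zip(blocks[:-1], blocks[1:]):
            assert a.end_sample == b.start_sample

    def test_eight_trial_partition_property(self):
        grid = Trace(np.zeros(4600), fs=10)
        timing = self._timing(8)
        blocks = build_blocks(timing, [HIGH] * 8, grid)
        covered = np.zeros(len(grid), dtype=int)
        for b in blocks:
            covered[b.slice()] += 1
        assert np.all(covered == 1)

    def test_overlapping_trials_rejected(self):
        with pytest.raises(ValueError):
            TaskTiming(trials=[(0.0, 5.0, 20.0, 30.0), (15.0, 18.0, 40.0, 50.0)])


class TestSegments:
    def _blocks(self, labels):
        from bhcvr.quality import BreathHoldBlock

        return [
            BreathHoldBlock(i, i * 100, (i + 1) * 100, quality=lab)
            for i, lab in enumerate(labels)
        ]

    def test_segments_avoid_low_blocks(self):
        blocks = self._blocks([HIGH, HIGH, HIGH, LOW, HIGH, HIGH])
        for seed in range(20):
            for first, last in segment_for_training(blocks, rng_seed=seed):
                assert all(blocks[j].quality != LOW for j in range(first, last))
                assert last - first >= 2

    def test_skipped_blocks_are_eligible(self):
        blocks = self._blocks([HIGH, SKIPPED, HIGH])
        segs = segment_for_training(blocks, rng_seed=0)
        assert segs  # the whole run is eligible

    def test_all_low_yields_empty_with_warning(self):
        blocks = self._blocks([LOW, LOW, LOW])
        with pytest.warns(UserWarning):
            assert segment_for_training(blocks, rng_seed=0) == []

    def test_deterministic_given_seed(self):
        blocks = self._blocks([HIGH] * 8)
        assert segment_for_training(blocks, 42) == segment_for_training(blocks, 42)

    def test_between_one_and_four_segments(self):
        blocks = self._blocks([HIGH] * 8)
        for seed in range(30):
            n = len(segment_for_training(blocks, seed))
            assert 1 <= n <= 4
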