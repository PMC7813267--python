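import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_epochs
from erpwp import synth
from erpwp.artifacts import (
    CleaningReport,
    amplitude_mask,
    include_subject,
    reject_amplitude,
    reject_by_annotations,
    summarize_cleaning,
)
from erpwp.io_core import CONDITIONS, Annotation, AnnotationList


def brute_force_mask(data, abs_thr, range_thr, w):
    """Independent per-window enumeration of both rejection rules."""
    n_trials, n_ch, n_samp = data.shape
    bad = np.zeros(n_trials, dtype=bool)
    for i in range(n_trials):
        if np.abs(data[i]).max() > abs_thr:
            bad[i] = True
            continue
        for start in range(n_samp - w + 1):
            seg = data[i, :, start:start + w]
            if (seg.max(axis=1) - seg.min(axis=1)).max() > range_thr:
                bad[i] = True
                break
    return bad


class TestAmplitudeRejection:
    def test_all_zero_trial_retained(self):
        ep = make_epochs(np.zeros((3, 2, 300)))
        out = reject_amplitude(ep, 150.0, 150.0)
        assert out.keep.all()

    def test_single_large_sample_rejected_by_absolute_rule(self):
        data = np.zeros((2, 2, 300))
        data[1, 0, 150] = 200.0
        ep = make_epochs(data)
        out = reject_amplitude(ep, 150.0, 150.0)
        assert list(out.keep) == [True, False]
        assert out.rejection_reason[1] == "amplitude"

    def test_fast_range_within_window_rejected(self):
        # 120 µV swing inside 100 ms, all samples within ±100 µV
        data = np.zeros((1, 2, 1201))
        data[0, 0, 500:530] = 90.0
        data[0, 0, 530:560] = -90.0
        ep = make_epochs(data)
        assert amplitude_mask(ep, 1000.0, 150.0).all()

    def test_slow_drift_not_rejected_by_range_rule(self):
        # same 180 µV swing spread over the whole epoch: no 100 ms window
        # sees more than the threshold
        ramp = np.linspace(-90, 90, 1201)
        ep = make_epochs(np.tile(ramp, (1, 2, 1)))
        assert not amplitude_mask(ep, 1000.0, 150.0).any()

    def test_mask_matches_bruteforce_enumeration(self, rng):
        data = rng.normal(0, 60, (300, 2, 400))
        ep = make_epochs(data)
        w = int(round(100.0 * 1000.0 / 1000.0)) + 1
        expected = brute_force_mask(data, 150.0, 150.0, w)
        got = amplitude_mask(ep, 150.0, 150.0)
        np.testing.assert_array_equal(got, expected)

    @pytest.mark.parametrize("abs_thr,range_thr", [(100.0, 120.0),
                                                   (150.0, 150.0)])
    def test_monotone_in_thresholds(self, rng, abs_thr, range_thr):
        ep = make_epochs(rng.normal(0, 55, (200, 2, 300)))
        loose = amplitude_mask(ep, abs_thr, range_thr)
        tight = amplitude_mask(ep, abs_thr * 0.8, range_thr * 0.8)
        assert (tight | loose).sum() == tight.sum()  # loose ⊆ tight

    def test_nonpositive_threshold_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            amplitude_mask(small_epochs, -1.0, 100.0)

    @given(st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mask_equals_bruteforce_on_arbitrary_trials(self, data):
        """Property: for arbitrary trial data and thresholds, the vectorized
        mask equals direct per-window enumeration."""
        n_samp = data.draw(st.integers(120, 240))
        n_trials = data.draw(st.integers(1, 6))
        abs_thr = data.draw(st.floats(20, 200))
        rng_thr = data.draw(st.floats(20, 200))
        seed = data.draw(st.integers(0, 2 ** 16))
        arr = np.random.default_rng(seed).normal(
            0, 60, (n_trials, 2, n_samp))
        ep = make_epochs(arr)
        got = amplitude_mask(ep, abs_thr, rng_thr)
        expected = brute_force_mask(arr, abs_thr, rng_thr, 101)
        np.testing.assert_array_equal(got, expected)


class TestAnnotationRejection:
    def _events(self, onsets_s, fs=1000.0):
        from erpwp.io_core import Event, EventList
        conds = ["WORDS", "SIMILAR", "NONSENSE"]
        return EventList([Event(int(o * fs), conds[i % 3], f"s{i}", 1, 1)
                          for i, o in enumerate(onsets_s)], fs)

    def test_no_annotations_leaves_mask_unchanged(self, rng):
        ep = make_epochs(rng.normal(size=(3, 2, 300)))
        ev = self._events([5.0, 10.0, 15.0])
        out = reject_by_annotations(ep, ev, AnnotationList())
        assert out.keep.all()

    def test_zero_length_boundary_overlap_retained(self, rng):
        ep = make_epochs(rng.normal(size=(1, 2, 300)))
        ev = self._events([5.0])
        # annotation ends exactly where the trial window starts (4.5 s)
        anns = AnnotationList([Annotation(4.0, 4.5, "movement")])
        out = reject_by_annotations(ep, ev, anns)
        assert out.keep.all()

    def test_positive_overlap_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(2, 2, 300)))
        ev = self._events([5.0, 10.0])
        anns = AnnotationList([Annotation(5.9, 6.1, "movement")])
        out = reject_by_annotations(ep, ev, anns)
        assert list(out.keep) == [False, True]
        assert out.rejection_reason[0] == "annotation"

    def test_ground_truth_movements_all_rejected(self):
        """Every trial whose window contains an injected movement burst is
        rejected when cleaning uses the generator's ground-truth log."""
        import dataclasses

        spec = dataclasses.replace(synth.CohortSpec(),
                                   movement_rate_hz=0.1, blink_rate_hz=0.0,
                                   n_subjects=1)
        cov = synth.default_covariates(1, seed=3)
        sub = synth.simulate_cohort(spec, cov)[0]
        from erpwp.preprocess import epoch_recording
        ep = epoch_recording(sub.recording, sub.events)
        out = reject_by_annotations(ep, sub.events, sub.annotations)
        onsets = sub.events.onsets / 1000.0
        should_reject = np.zeros(len(onsets), dtype=bool)
        for ann in sub.annotations:
            should_reject |= (np.minimum(onsets + 1.0, ann.end_s)
                              - np.maximum(onsets - 0.5, ann.start_s)) > 0
        assert should_reject.sum() > 0
        np.testing.assert_array_equal(~out.keep, should_reject)


class TestInclusionAndSummary:
    def _report(self, clean, total=80):
        n_total = {c: total for c in CONDITIONS}
        zero = {c: 0 for c in CONDITIONS}
        n_clean = dict(zip(CONDITIONS, clean))
        n_amp = {c: total - n_clean[c] for c in CONDITIONS}
        return CleaningReport("s", n_total, n_amp, zero, n_clean)

    def test_exact_minimum_included(self):
        assert include_subject(self._report((10, 10, 10)))

    def test_one_short_condition_excluded(self):
        assert not include_subject(self._report((9, 80, 80)))

    def test_published_mean_trial_counts_pass_inclusion(self):
        assert include_subject(self._report((19, 21, 19)))

    def test_all_clean_summary_is_zero_percent(self):
        reports = [self._report((80, 80, 80)) for _ in range(3)]
        summary = summarize_cleaning(reports)
        assert summary.percent_rejected == 0.0
        assert summary.included == ["s", "s", "s"]

    def test_half_rejected_everywhere_is_fifty_percent(self):
        reports = [self._report((40, 40, 40)) for _ in range(4)]
        assert summarize_cleaning(reports).percent_rejected == 50.0

    def test_summary_matches_recount(self, rng):
        reports = [self._report(tuple(rng.integers(0, 81, 3)))
                   for _ in range(6)]
        summary = summarize_cleaning(reports)
        total = 6 * 3 * 80
        clean = sum(sum(r.n_clean.values()) for r in reports)
        assert summary.percent_rejected == pytest.approx(
            100 * (total - clean) / total)
        for c in CONDITIONS:
            counts = [r.n_clean[c] for r in reports]
            assert summary.per_condition[c]["mean"] == pytest.approx(
                np.mean(counts))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CleaningReport("s", {c: 80 for c in CONDITIONS},
                           {c: 5 for c in CONDITIONS},
                           {c: 0 for c in CONDITIONS},
                           {c: 80 for c in CONDITIONS})
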