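"""Event generation (run removal + gap filling) and 70%-coverage matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from szevents.events import (
    EventList,
    PostprocessParams,
    evaluate_subject,
    generate_events,
    match_events,
    score_events,
    truth_events,
)
from szevents.io import EEGRecord, SeizureAnnotation, ValidationError, build_timeline
from szevents.segment import LabelSequence, true_label_sequence


def seq(bits):
    return LabelSequence(subject_id="s1", labels=np.array(list(bits), dtype=np.int8))


def bruteforce_postprocess(bits, min_event_s=10.0, max_gap_s=10.0, seg=5.0):
    """Independent reference via itertools.groupby run-length encoding."""
    y = list(bits)
    runs = [(k, len(list(g))) for k, g in itertools.groupby(y)]
    # delete short seizure runs
    out, pos = y[:], 0
    for val, ln in runs:
        if val == 1 and ln * seg <= min_event_s + 1e-9:
            out[pos : pos + ln] = [0] * ln
        pos += ln
    # fill short gaps between surviving seizure runs
    runs2, pos, ones = [(k, len(list(g))) for k, g in itertools.groupby(out)], 0, []
    for val, ln in runs2:
        if val == 1:
            ones.append((pos, pos + ln))
        pos += ln
    for (a, b), (c, d) in zip(ones, ones[1:]):
        if (c - b) * seg <= max_gap_s + 1e-9:
            out[b:c] = [1] * (c - b)
    events = []
    pos = 0
    for val, ln in [(k, len(list(g))) for k, g in itertools.groupby(out)]:
        if val == 1:
            events.append((pos * seg, (pos + ln) * seg))
        pos += ln
    return out, events


class TestGenerateEvents:
    def test_isolated_ten_second_run_removed(self):
        cleaned, events = generate_events(seq([0, 0, 1, 1, 0, 0]))
        assert cleaned.labels.sum() == 0
        assert len(events) == 0

    def test_short_gap_merges_into_single_event(self):
        cleaned, events = generate_events(seq([1, 1, 1, 0, 0, 1, 1, 1]))
        assert list(cleaned.labels) == [1] * 8
        assert len(events) == 1
        assert tuple(events.intervals[0]) == (0.0, 40.0)

    def test_seven_runs_collapse_to_three_events(self):
        # two isolated runs <= 10 s, five runs >= 15 s with two gaps <= 10 s
        bits = (
            [1, 1] + [0] * 4          # isolated 10 s run -> removed
            + [1, 1, 1] + [0, 0] + [1, 1, 1]   # merged -> event 1
            + [0] * 5
            + [1] + [0] * 4           # isolated 5 s run -> removed
            + [1, 1, 1, 1] + [0, 0] + [1, 1, 1]  # merged -> event 2
            + [0] * 5
            + [1, 1, 1, 1, 1]         # event 3
        )
        assert sum(1 for k, _ in itertools.groupby(bits) if k == 1) == 7
        _, events = generate_events(seq(bits))
        assert len(events) == 3

    def test_removal_happens_before_gap_filling(self):
        # a short run between two long runs is deleted first, leaving a
        # 25 s gap that is too wide to fill
        bits = [1, 1, 1] + [0, 0] + [1] + [0, 0] + [1, 1, 1]
        _, events = generate_events(seq(bits))
        assert len(events) == 2

    def test_empty_and_allzero_sequences(self):
        for bits in ([], [0, 0, 0, 0]):
            cleaned, events = generate_events(seq(bits))
            assert len(events) == 0
            assert cleaned.labels.sum() == 0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 1), max_size=80))
    def test_idempotent(self, bits):
        once, _ = generate_events(seq(bits))
        twice, ev2 = generate_events(once)
        assert np.array_equal(once.labels, twice.labels)
        for val, a, b in _runs_of(twice.labels):
            if val == 1:
                assert (b - a) * 5 > 10

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.integers(0, 1), max_size=60))
    def test_matches_bruteforce(self, bits):
        cleaned, events = generate_events(seq(bits))
        ref_labels, ref_events = bruteforce_postprocess(bits)
        assert list(cleaned.labels) == ref_labels
        assert [tuple(e) for e in events.intervals] == ref_events


def _runs_of(labels):
    out, pos = [], 0
    for k, g in itertools.groupby(list(labels)):
        ln = len(list(g))
        out.append((k, pos, pos + ln))
        pos += ln
    return out


def ev(*intervals):
    return EventList(np.array(intervals, dtype=float).reshape(-1, 2))


class TestMatchEvents:
    def test_seventy_percent_boundary_inclusive(self):
        m = match_events(ev((0, 100)), ev((10, 80)))
        assert (m.tp, m.missed, m.fp) == (1, 0, 0)

    def test_sixty_percent_is_discarded_not_fp(self):
        m = match_events(ev((0, 100)), ev((10, 70)))
        assert (m.tp, m.missed, m.fp) == (0, 1, 0)

    def test_partial_overlap_as_fp_flag(self):
        m = match_events(
            ev((0, 100)), ev((10, 70)), PostprocessParams(partial_overlap_as_fp=True)
        )
        assert (m.tp, m.missed, m.fp) == (0, 1, 1)

    def test_fragmented_coverage_pools_to_single_tp(self):
        # three fragments pooling 75 s of a 100 s event: one TP, region M forgiven
        m = match_events(ev((0, 100)), ev((0, 30), (40, 70), (85, 100)))
        assert (m.tp, m.fp) == (1, 0)
        assert m.coverages[0] == pytest.approx(0.75)

    def test_worked_example_five_true_three_covered_six_spurious(self):
        truth = ev(*[(i * 1000, i * 1000 + 100) for i in range(5)])
        detected = ev(
            (0, 80), (1010, 1090), (2000, 2075),          # cover events 0-2
            *[(5000 + 200 * k, 5000 + 200 * k + 30) for k in range(6)],  # spurious
        )
        m = match_events(truth, detected)
        assert (m.tp, m.missed, m.fp) == (3, 2, 6)
        s = score_events(m, hours=2.0)
        assert s.sensitivity_pct == pytest.approx(60.0)
        assert s.fdr_per_h == pytest.approx(3.0)

    def test_conservation_and_bucket_partition(self, rng):
        for _ in range(50):
            t = np.cumsum(rng.integers(5, 60, size=8)).astype(float)
            truth = ev(*zip(t[::2], t[1::2]))
            d = np.cumsum(rng.integers(3, 50, size=12)).astype(float)
            detected = ev(*zip(d[::2], d[1::2]))
            m = match_events(truth, detected)
            assert m.tp + m.missed == len(truth)
            assert 0 <= m.fp <= len(detected)

    def test_added_disjoint_detection_adds_exactly_one_fp(self, rng):
        truth = ev((100, 200), (400, 480))
        detected = ev((110, 190))
        base = match_events(truth, detected)
        more = match_events(truth, ev((110, 190), (1000, 1020)))
        assert more.fp == base.fp + 1
        assert more.tp == base.tp


class TestScoreEvents:
    def test_zero_true_events_sensitivity_zero(self):
        s = score_events(match_events(ev(), ev((0, 20))), hours=1.0)
        assert s.sensitivity_pct == 0.0
        assert s.fdr_per_h == 1.0

    def test_no_false_positives_zero_fdr(self):
        s = score_events(match_events(ev((0, 100)), ev((0, 100))), hours=5.0)
        assert s.fdr_per_h == 0.0
        assert s.sensitivity_pct == 100.0

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValidationError):
            score_events(match_events(ev(), ev()), hours=0.0)


def _timeline_with(anns_by_record, dur=150.0):
    recs = []
    t0 = 0.0
    for i, anns in enumerate(anns_by_record):
        rid = f"r{i}.edf"
        recs.append(
            EEGRecord(
                subject_id="s1", record_id=rid, start_time_s=t0, duration_s=dur,
                signal=np.zeros((22, int(dur * 256)), dtype=np.float32),
                annotations=[SeizureAnnotation(rid, a, b) for a, b in anns],
            )
        )
        t0 += dur + 30.0
    return build_timeline(recs)


class TestTruthEventsAndEvaluate:
    def test_truth_collapses_gaps_and_merges_boundary_seizure(self):
        tl = _timeline_with([[(140, 150)], [(0, 20)]])
        t = truth_events(tl)
        assert len(t) == 1
        assert tuple(t.intervals[0]) == (140.0, 170.0)

    def test_perfect_predictions_score_100_and_zero_fdr(self):
        tl = _timeline_with([[(50, 80)], []])
        truth_seq = true_label_sequence(tl)
        preds = pd.DataFrame(
            {
                "subject": "s1",
                "record": truth_seq.record_ids,
                "index": truth_seq.record_indices,
                "y_pred": truth_seq.labels,
            }
        )
        score, m, _ = evaluate_subject(preds, tl)
        assert score.sensitivity_pct == 100.0
        assert score.fdr_per_h == 0.0
        assert score.hours == pytest.approx(300 / 3600)

    def test_inserted_short_false_run_removed_by_postprocessing(self):
        tl = _timeline_with([[(50, 80)], []])
        truth_seq = true_label_sequence(tl)
        y = truth_seq.labels.copy()
        y[40] = 1  # one isolated 5 s false segment
        preds = pd.DataFrame(
            {
                "subject": "s1",
                "record": truth_seq.record_ids,
                "index": truth_seq.record_indices,
                "y_pred": y,
            }
        )
        score, _, _ = evaluate_subject(preds, tl)
        assert score.fdr_per_h == 0.0
        assert score.sensitivity_pct == 100.0

    def test_random_predictions_on_seizure_free_timeline(self, rng):
        tl = _timeline_with([[], [], [], []], dur=300.0)
        truth_seq = true_label_sequence(tl)
        preds = pd.DataFrame(
            {
                "subject": "s1",
                "record": truth_seq.record_ids,
                "index": truth_seq.record_indices,
                "y_pred": rng.integers(0, 2, size=len(truth_seq)),
            }
        )
        score, _, _ = evaluate_subject(preds, tl)
        assert score.sensitivity_pct == 0.0
        assert score.fdr_per_h > 0.0

    def test_missing_predictions_listed(self):
        tl = _timeline_with([[(50, 80)]])
        preds = pd.DataFrame(
            {"subject": "s1", "record": "r0.edf", "index": [0, 1], "y_pred": [0, 0]}
        )
        with pytest.raises(ValidationError, match="missing predictions"):
            evaluate_subject(preds, tl)
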