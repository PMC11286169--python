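"""Segment-to-event post-processing and event-level scoring.

Per-segment classifier outputs on a subject timeline are turned into
seizure events in two steps: (1) predicted seizure runs of total
duration <= 10 s are deleted (too short to be a clinical event), then
(2) non-seizure gaps <= 10 s lying between two surviving seizure runs
are filled, merging them.  Both thresholds are inclusive and the
composite is idempotent.

Detected events are matched to true events by coverage: a true event
counts as detected (TP) when the pooled detected-seizure time inside it
reaches 70% of its duration, credited once however many detected
fragments contribute.  Missed fragments inside a matched event are
forgiven (region "M"); detected fragments overlapping a *failed* true
event are discarded — neither TP nor FP (region "X"); every detected
event with zero overlap with all true events counts one false positive.

Scores are the clinical pair: event sensitivity (percent of true events
detected) and false detection rate (false positives per hour observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SubjectTimeline, ValidationError
from .segment import LabelSequence, WINDOW_S, segment_count

__all__ = [
    "PostprocessParams",
    "EventList",
    "EventMatchResult",
    "EventScore",
    "generate_events",
    "match_events",
    "score_events",
    "truth_events",
    "evaluate_subject",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PostprocessParams:
    min_event_s: float = 10.0     # seizure runs <= this are deleted
    max_gap_s: float = 10.0       # gaps <= this between runs are filled
    coverage: float = 0.70        # fraction of a true event to credit a TP
    segment_s: float = WINDOW_S
    partial_overlap_as_fp: bool = False  # count X-region fragments as FP

    def __post_init__(self) -> None:
        if min(self.min_event_s, self.max_gap_s, self.segment_s) <= 0:
            raise ValidationError("durations must be positive")
        if not (0 < self.coverage <= 1):
            raise ValidationError("coverage must be in (0, 1]")


@dataclass
class EventList:
    """Sorted, non-overlapping half-open intervals [start_s, end_s)."""

    intervals: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if len(iv) and not (iv[:, 1] > iv[:, 0]).all():
            raise ValidationError("event end must exceed start")
        order = np.argsort(iv[:, 0]) if len(iv) else np.array([], dtype=int)
        iv = iv[order]
        if len(iv) > 1 and (iv[1:, 0] < iv[:-1, 1]).any():
            raise ValidationError("events must not overlap")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


@dataclass
class EventMatchResult:
    tp: int
    missed: int
    fp: int
    coverages: np.ndarray  # per-true-event pooled coverage fraction


@dataclass
class EventScore:
    sensitivity_pct: float
    fdr_per_h: float
    hours: float
    tp: int = 0
    missed: int = 0
    fp: int = 0


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a binary vector as (value, start, stop) triples."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [
        (int(labels[bounds[i]]), int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
    ]


def generate_events(
    labels: LabelSequence, params: PostprocessParams = PostprocessParams()
) -> tuple[LabelSequence, EventList]:
    """Clean a predicted label sequence and list its seizure events.

    Short-run deletion happens before gap filling (runs are judged on
    the raw sequence; gaps on the cleaned one).  The output has all
    seizure runs and all internal gaps strictly longer than 10 s, which
    makes the operation idempotent.
    """
    y = labels.labels.astype(np.int8).copy()
    seg = labels.segment_s

    # step 1: delete too-short seizure runs
    for val, a, b in _runs(y):
        if val == 1 and (b - a) * seg <= params.min_event_s + 1e-9:
            y[a:b] = 0

    # step 2: fill short gaps between surviving runs
    ones = [(a, b) for val, a, b in _runs(y) if val == 1]
    for (_, b_prev), (a_next, _) in zip(ones, ones[1:]):
        if (a_next - b_prev) * seg <= params.max_gap_s + 1e-9:
            y[b_prev:a_next] = 1

    cleaned = LabelSequence(
        subject_id=labels.subject_id,
        labels=y,
        segment_s=seg,
        record_ids=labels.record_ids,
        record_indices=labels.record_indices,
    )
    iv = [(a * seg, b * seg) for val, a, b in _runs(y) if val == 1]
    return cleaned, EventList(np.array(iv).reshape(-1, 2))


def match_events(
    truth: EventList,
    detected: EventList,
    params: PostprocessParams = PostprocessParams(),
) -> EventMatchResult:
    """Coverage-based event matching (strict 70%-overlap convention).

    Every detected event ends up in exactly one bucket: contributing to
    a matched true event, X-discarded (overlaps only failed true
    events), or FP (zero overlap with all true events).
    """
    T = truth.intervals
    D = detected.intervals
    cov_time = np.zeros(len(T))
    overlaps = np.zeros((len(T), len(D)))
    for i, (ts, te) in enumerate(T):
        if len(D):
            inter = np.clip(np.minimum(te, D[:, 1]) - np.maximum(ts, D[:, 0]), 0, None)
            overlaps[i] = inter
            cov_time[i] = inter.sum()
    durations = T[:, 1] - T[:, 0] if len(T) else np.array([])
    coverages = cov_time / durations if len(T) else np.array([])
    matched = coverages >= params.coverage - 1e-12
    tp = int(matched.sum())
    missed = len(T) - tp

    fp = 0
    for j in range(len(D)):
        ov = overlaps[:, j] if len(T) else np.array([])
        if len(T) and (ov[matched] > 0).any():
            continue  # contributes to a TP
        if len(T) and (ov > 0).any():
            if params.partial_overlap_as_fp:
                fp += 1
            continue  # X region: partial detection of a failed event
        fp += 1  # zero overlap with every true event
    return EventMatchResult(tp=tp, missed=missed, fp=fp, coverages=coverages)


def score_events(match: EventMatchResult, hours: float) -> EventScore:
    """Sensitivity (%) and false detections per hour from a match result."""
    if hours <= 0:
        raise ValidationError("hours observed must be positive")
    n_true = match.tp + match.missed
    if n_true == 0:
        logger.warning("no true events on this timeline; sensitivity reported as 0")
        sen = 0.0
    else:
        sen = 100.0 * match.tp / n_true
    return EventScore(
        sensitivity_pct=sen,
        fdr_per_h=match.fp / hours,
        hours=hours,
        tp=match.tp,
        missed=match.missed,
        fp=match.fp,
    )


def truth_events(timeline: SubjectTimeline, segment_s: float = WINDOW_S) -> EventList:
    """True seizure intervals mapped onto the collapsed subject timeline.

    Record k's segment block starts at 5 s * (segments of records before
    it); annotation times are clipped to the segmented extent of their
    record (trailing sub-window remainders carry no segments).  Pieces
    that become adjacent across a record boundary are merged.
    """
    iv = []
    base = 0.0
    for rec in timeline.records:
        n = segment_count(rec.duration_s, segment_s)
        span = n * segment_s
        for a in rec.annotations:
            s, e = min(a.start_s, span), min(a.end_s, span)
            if e > s:
                iv.append((base + s, base + e))
        base += span
    # merge touching pieces (e.g. a seizure spanning a record boundary)
    iv.sort()
    merged: list[list[float]] = []
    for s, e in iv:
        if merged and s <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return EventList(np.array(merged).reshape(-1, 2))


def predictions_to_sequence(
    predictions: pd.DataFrame, timeline: SubjectTimeline, segment_s: float = WINDOW_S
) -> LabelSequence:
    """Order per-segment predictions along the collapsed timeline.

    ``predictions`` needs columns (subject, record, index, y_pred).
    Raises listing the gaps if any timeline segment lacks a prediction.
    """
    sub = predictions[predictions["subject"] == timeline.subject_id]
    lut = {(r, int(i)): int(p) for r, i, p in zip(sub["record"], sub["index"], sub["y_pred"])}
    labels = []
    missing = []
    for rec in timeline.records:
        for i in range(segment_count(rec.duration_s, segment_s)):
            key = (rec.record_id, i)
            if key not in lut:
                missing.append(key)
            else:
                labels.append(lut[key])
    if missing:
        raise ValidationError(
            f"{timeline.subject_id}: missing predictions for "
            f"{len(missing)} segments, first {missing[:5]}"
        )
    return LabelSequence(
        subject_id=timeline.subject_id,
        labels=np.array(labels, dtype=np.int8),
        segment_s=segment_s,
    )


def evaluate_subject(
    predictions: pd.DataFrame,
    timeline: SubjectTimeline,
    params: PostprocessParams = PostprocessParams(),
) -> tuple[EventScore, EventMatchResult, EventList]:
    """Event-level evaluation of one subject from per-segment predictions.

    Assembles the predicted label sequence in record temporal order,
    post-processes it into events, matches against the full annotated
    truth events, and scores with hours = total timeline duration.
    """
    seq = predictions_to_sequence(predictions, timeline, params.segment_s)
    _, detected = generate_events(seq, params)
    truth = truth_events(timeline, params.segment_s)
    m = match_events(truth, detected, params)
    hours = timeline.total_duration_s / 3600.0
    return score_events(m, hours), m, detected


def score_table(
    predictions: pd.DataFrame,
    timelines: list[SubjectTimeline],
    params: PostprocessParams = PostprocessParams(),
) -> pd.DataFrame:
    """Per-subject and overall event scores, one row per subject + 'overall'.

    Overall sensitivity/FDR are averages of the per-subject scores, the
    convention used for cross-subject event reporting.
    """
    rows = []
    for tl in timelines:
        score, m, _ = evaluate_subject(predictions, tl, params)
        rows.append(
            {
                "subject": tl.subject_id,
                "sz": m.tp + m.missed,
                "tp": m.tp,
                "fp": m.fp,
                "sen_pct": score.sensitivity_pct,
                "fdr_per_h": score.fdr_per_h,
                "hours": score.hours,
            }
        )
    df = pd.DataFrame(rows)
    overall = {
        "subject": "overall",
        "sz": int(df["sz"].sum()),
        "tp": int(df["tp"].sum()),
        "fp": int(df["fp"].sum()),
        "sen_pct": float(df["sen_pct"].mean()),
        "fdr_per_h": float(df["fdr_per_h"].mean()),
        "hours": float(df["hours"].sum()),
    }
    return pd.concat([df, pd.DataFrame([overall])], ignore_index=True)
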