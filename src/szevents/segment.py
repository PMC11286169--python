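"""Segmentation of records into 5-s windows and ictal labeling.

Each record is cut into non-overlapping fixed windows (default 5 s); a
trailing remainder shorter than the window is dropped.  A window is
labeled ictal (1) when it overlaps annotated seizure time by at least
60% of the window (3 s for 5-s windows), the threshold being inclusive;
overlap with multiple annotations is summed before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecord, SubjectTimeline, ValidationError

__all__ = [
    "WINDOW_S",
    "LABEL_THRESHOLD_FRACTION",
    "Segment",
    "segment_record",
    "segment_count",
    "label_segment",
    "LabelSequence",
    "true_label_sequence",
]

WINDOW_S = 5.0
LABEL_THRESHOLD_FRACTION = 0.60


@dataclass(frozen=True)
class Segment:
    """One window of one record, with its ictal-overlap bookkeeping."""

    subject_id: str
    record_id: str
    index: int            # 0-based window ordinal within the record
    t_start_s: float      # record-relative
    t_end_s: float
    seizure_overlap_s: float
    label: int


def segment_count(duration_s: float, window_s: float = WINDOW_S) -> int:
    return int(np.floor(duration_s / window_s + 1e-9))


def label_segment(
    overlap_s: float,
    threshold_fraction: float = LABEL_THRESHOLD_FRACTION,
    window_s: float = WINDOW_S,
) -> int:
    """Binary ictal label from seizure overlap; inclusive at threshold."""
    if not (0.0 <= overlap_s <= window_s + 1e-9):
        raise ValidationError(f"overlap {overlap_s} outside [0, {window_s}]")
    return int(overlap_s >= threshold_fraction * window_s - 1e-9)


def segment_record(record: EEGRecord, window_s: float = WINDOW_S) -> list[Segment]:
    """Cut a record into labeled non-overlapping windows.

    Returns ``floor(duration / window)`` segments; a record shorter than
    one window yields an empty list.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    n = segment_count(record.duration_s, window_s)
    starts = np.arange(n) * window_s
    ends = starts + window_s
    overlap = np.zeros(n)
    for a in record.annotations:
        overlap += np.clip(
            np.minimum(ends, a.end_s) - np.maximum(starts, a.start_s), 0.0, None
        )
    return [
        Segment(
            subject_id=record.subject_id,
            record_id=record.record_id,
            index=i,
            t_start_s=float(starts[i]),
            t_end_s=float(ends[i]),
            seizure_overlap_s=float(min(overlap[i], window_s)),
            label=label_segment(float(min(overlap[i], window_s)), window_s=window_s),
        )
        for i in range(n)
    ]


@dataclass
class LabelSequence:
    """Binary per-segment labels on one subject's collapsed timeline.

    Index ``i`` covers collapsed-time ``[i*segment_s, (i+1)*segment_s)``;
    ``record_ids``/``record_indices`` keep the provenance of each entry.
    Inter-record gaps are collapsed: the sequence is the concatenation of
    per-record segment labels in temporal order.
    """

    subject_id: str
    labels: np.ndarray
    segment_s: float = WINDOW_S
    record_ids: list[str] | None = None
    record_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be one-dimensional")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.segment_s


def true_label_sequence(
    timeline: SubjectTimeline, window_s: float = WINDOW_S
) -> LabelSequence:
    """Ground-truth label sequence of a subject timeline.

    Records are segmented independently and their label vectors
    concatenated in temporal order.
    """
    labels: list[int] = []
    rec_ids: list[str] = []
    rec_idx: list[int] = []
    for rec in timeline.records:
        for seg in segment_record(rec, window_s):
            labels.append(seg.label)
            rec_ids.append(rec.record_id)
            rec_idx.append(seg.index)
    return LabelSequence(
        subject_id=timeline.subject_id,
        labels=np.array(labels, dtype=np.int8),
        segment_s=window_s,
        record_ids=rec_ids,
        record_indices=np.array(rec_idx, dtype=np.int64),
    )
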