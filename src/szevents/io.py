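"""Reading and validation of CHB-MIT-style EEG recordings.

Continuous scalp EEG in this corpus layout comes as one EDF file per
record plus a per-subject plain-text annotation summary giving, for each
file, its wall-clock start/end times and the seizure start/end offsets in
seconds.  This module parses that dialect, reads EDF signals restricted
to the canonical 22-channel bipolar montage, and assembles per-subject
temporally ordered timelines on which event detection operates.

Records that do not carry the full canonical channel group are rejected
with :class:`ChannelGroupMismatch` (the corpus itself mixes five montage
groups; only the majority group is supported).  Signals are never
filtered, rescaled or otherwise altered on the way in.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_CHANNELS",
    "ChannelGroup",
    "ChannelGroupMismatch",
    "SummaryParseError",
    "ValidationError",
    "SeizureAnnotation",
    "EEGRecord",
    "SubjectTimeline",
    "parse_summary",
    "write_summary",
    "read_record",
    "write_edf",
    "read_edf_signal",
    "build_timeline",
    "load_subject",
    "load_manifest",
]

#: Canonical 22-channel bipolar montage, fixed order.  This is the channel
#: group shared by the large majority of records in the corpus.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8",
)

FS = 256  #: sampling rate in Hz, constant across the corpus


class SummaryParseError(ValueError):
    """A summary file block could not be parsed; message names the line."""


class ChannelGroupMismatch(ValueError):
    """An EDF does not contain the full canonical channel group."""


class ValidationError(ValueError):
    """A domain invariant was violated (times, overlaps, shapes)."""


@dataclass(frozen=True)
class ChannelGroup:
    """Ordered group of channel labels; default is the canonical 22."""

    labels: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValidationError("channel labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure interval, in seconds from the start of its record."""

    record_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValidationError(
                f"{self.record_id}: seizure must have 0 <= start < end, "
                f"got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """One continuous multi-channel recording on a subject timeline.

    ``signal`` is a (22, duration_s * fs) array in microvolts, channels in
    canonical order.  ``start_time_s`` positions the record on the subject
    clock (seconds since the subject's first record's midnight).
    """

    subject_id: str
    record_id: str
    start_time_s: float
    duration_s: float
    signal: np.ndarray
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    fs: int = FS
    channels: ChannelGroup = field(default_factory=ChannelGroup)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValidationError(
                f"{self.record_id}: signal must be ({len(self.channels)}, n) "
                f"got {self.signal.shape}"
            )
        n_expected = int(round(self.duration_s * self.fs))
        if self.signal.shape[1] != n_expected:
            raise ValidationError(
                f"{self.record_id}: expected {n_expected} samples "
                f"({self.duration_s} s at {self.fs} Hz), got {self.signal.shape[1]}"
            )
        anns = sorted(self.annotations, key=lambda a: a.start_s)
        for a in anns:
            if a.end_s > self.duration_s:
                raise ValidationError(
                    f"{self.record_id}: annotation [{a.start_s}, {a.end_s}] "
                    f"exceeds record duration {self.duration_s}"
                )
        for a, b in zip(anns, anns[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(
                    f"{self.record_id}: overlapping annotations "
                    f"[{a.start_s},{a.end_s}] and [{b.start_s},{b.end_s}]"
                )
        self.annotations = anns

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s


@dataclass
class SubjectTimeline:
    """Temporally ordered records of one subject.

    Downstream event logic treats consecutive records as contiguous
    (inter-record gaps collapsed), matching the corpus description of
    per-subject recordings as continuous.
    """

    subject_id: str
    records: list[EEGRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.subject_id != self.subject_id:
                raise ValidationError(
                    f"record {r.record_id} belongs to {r.subject_id}, "
                    f"not {self.subject_id}"
                )
        self.records = sorted(self.records, key=lambda r: r.start_time_s)
        for a, b in zip(self.records, self.records[1:]):
            if b.start_time_s < a.end_time_s:
                raise ValidationError(
                    f"records {a.record_id} and {b.record_id} overlap in time"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(r.duration_s for r in self.records)

    @property
    def annotations(self) -> list[SeizureAnnotation]:
        return [a for r in self.records for a in r.annotations]


# ---------------------------------------------------------------------------
# Annotation summary dialect
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"^(\d{1,2}):(\d{2}):(\d{2})$")


def _clock_to_seconds(text: str, line_no: int) -> int:
    m = _TIME_RE.match(text.strip())
    if m is None:
        raise SummaryParseError(f"line {line_no}: cannot parse clock time {text!r}")
    h, mi, s = (int(g) for g in m.groups())
    if mi >= 60 or s >= 60:
        raise SummaryParseError(f"line {line_no}: invalid clock time {text!r}")
    # hours may legitimately exceed 23 in this dialect (post-midnight files)
    return 3600 * h + 60 * mi + s


_SEIZURE_START_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+Start\s+Time\s*:\s*(\d+(?:\.\d+)?)\s*sec", re.I
)
_SEIZURE_END_RE = re.compile(
    r"^Seizure(?:\s+\d+)?\s+End\s+Time\s*:\s*(\d+(?:\.\d+)?)\s*sec", re.I
)


def parse_summary(text: str) -> list[tuple[str, float, float, list[SeizureAnnotation]]]:
    """Parse a CHB-MIT-dialect annotation summary.

    Returns one ``(record_id, start_time_s, duration_s, annotations)``
    tuple per file block, in file order.  Clock times that wrap past
    midnight are corrected by adding 24 h whenever a start time precedes
    its predecessor's, so ``start_time_s`` is monotone along the summary.

    Raises :class:`SummaryParseError` naming the offending line on
    malformed blocks and :class:`ValidationError` on impossible seizure
    times (end <= start).
    """
    lines = text.splitlines()
    entries: list[tuple[str, float, float, list[SeizureAnnotation]]] = []

    i = 0
    n = len(lines)
    day_offset = 0.0
    prev_start: float | None = None
    while i < n:
        line = lines[i].strip()
        if not line.lower().startswith("file name"):
            i += 1
            continue
        if ":" not in line:
            raise SummaryParseError(f"line {i + 1}: malformed 'File Name' line")
        record_id = line.split(":", 1)[1].strip()
        if not record_id:
            raise SummaryParseError(f"line {i + 1}: empty file name")

        block: dict[str, tuple[str, int]] = {}
        seiz_starts: list[tuple[float, int]] = []
        seiz_ends: list[tuple[float, int]] = []
        i += 1
        while i < n and not lines[i].strip().lower().startswith("file name"):
            raw = lines[i].strip()
            i += 1
            if not raw:
                continue
            ms = _SEIZURE_START_RE.match(raw)
            me = _SEIZURE_END_RE.match(raw)
            if ms:
                seiz_starts.append((float(ms.group(1)), i))
            elif me:
                seiz_ends.append((float(me.group(1)), i))
            elif ":" in raw:
                key = raw.split(":", 1)[0].strip().lower()
                val = raw.split(":", 1)[1].strip()
                block[key] = (val, i)
            # other prose lines (channel lists etc.) are ignored

        for key in ("file start time", "file end time", "number of seizures in file"):
            if key not in block:
                raise SummaryParseError(
                    f"block for {record_id!r}: missing '{key.title()}' line"
                )
        start_raw, start_ln = block["file start time"]
        end_raw, end_ln = block["file end time"]
        n_seiz_raw, n_seiz_ln = block["number of seizures in file"]
        try:
            n_seiz = int(n_seiz_raw)
        except ValueError:
            raise SummaryParseError(
                f"line {n_seiz_ln}: bad seizure count {n_seiz_raw!r}"
            ) from None
        if len(seiz_starts) != n_seiz or len(seiz_ends) != n_seiz:
            raise SummaryParseError(
                f"block for {record_id!r}: declares {n_seiz} seizures but has "
                f"{len(seiz_starts)} start / {len(seiz_ends)} end lines"
            )

        start_s = float(_clock_to_seconds(start_raw, start_ln))
        end_s = float(_clock_to_seconds(end_raw, end_ln))
        if end_s < start_s:
            end_s += 86400.0  # record itself spans midnight
        start_s += day_offset
        end_s += day_offset
        if prev_start is not None and start_s < prev_start:
            day_offset += 86400.0
            start_s += 86400.0
            end_s += 86400.0
        prev_start = start_s
        duration_s = end_s - start_s

        anns = []
        for (s, ln), (e, _) in zip(seiz_starts, seiz_ends):
            if e <= s:
                raise ValidationError(
                    f"line {ln}: seizure end {e} <= start {s} in {record_id}"
                )
            anns.append(SeizureAnnotation(record_id, s, e))
        entries.append((record_id, start_s, duration_s, anns))

    return entries


def write_summary(
    entries: Iterable[tuple[str, float, float, list[SeizureAnnotation]]],
    fs: int = FS,
) -> str:
    """Serialize timeline entries back into the summary dialect.

    Inverse of :func:`parse_summary` up to clock-time representation
    (times are rendered modulo 24 h, as in the corpus files).
    """

    def clock(t: float) -> str:
        t = int(round(t)) % 86400
        return f"{t // 3600:02d}:{(t % 3600) // 60:02d}:{t % 60:02d}"

    out = [f"Data Sampling Rate: {fs} Hz", "*" * 25, ""]
    for record_id, start_s, duration_s, anns in entries:
        out.append(f"File Name: {record_id}")
        out.append(f"File Start Time: {clock(start_s)}")
        out.append(f"File End Time: {clock(start_s + duration_s)}")
        out.append(f"Number of Seizures in File: {len(anns)}")
        for k, a in enumerate(anns, start=1):
            out.append(f"Seizure {k} Start Time: {int(round(a.start_s))} seconds")
            out.append(f"Seizure {k} End Time: {int(round(a.end_s))} seconds")
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# EDF signal I/O
# ---------------------------------------------------------------------------


def write_edf(
    path: str | Path,
    signal: np.ndarray,
    labels: Sequence[str] = CANONICAL_CHANNELS,
    fs: int = FS,
) -> None:
    """Write a (n_channels, n_samples) microvolt matrix as 16-bit EDF.

    Minimal EDF: one-second data records, per-channel physical scaling
    chosen from the data range, digital range the full signed 16-bit
    span.  n_samples must be a whole number of seconds.
    """
    signal = np.asarray(signal, dtype=np.float64)
    nch, nsamp = signal.shape
    if len(labels) != nch:
        raise ValidationError("labels/signal channel count mismatch")
    if nsamp % fs:
        raise ValidationError("signal length must be a whole number of seconds")
    n_records = nsamp // fs

    phys_min = signal.min(axis=1)
    phys_max = signal.max(axis=1)
    # guard degenerate (constant) channels: give them a unit span
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValidationError(f"EDF header field too long: {s!r}")
        return b.ljust(width)

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2000 X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (nch + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(nch), 4),
        ]
    )
    per = b"".join(
        [
            b"".join(pad(lab, 16) for lab in labels),
            b"".join(pad("", 80) for _ in range(nch)),
            b"".join(pad("uV", 8) for _ in range(nch)),
            b"".join(pad(f"{phys_min[c]:.8g}"[:8], 8) for c in range(nch)),
            b"".join(pad(f"{phys_max[c]:.8g}"[:8], 8) for c in range(nch)),
            b"".join(pad(str(dig_min), 8) for _ in range(nch)),
            b"".join(pad(str(dig_max), 8) for _ in range(nch)),
            b"".join(pad("", 80) for _ in range(nch)),
            b"".join(pad(str(fs), 8) for _ in range(nch)),
            b"".join(pad("", 32) for _ in range(nch)),
        ]
    )

    # header fields are re-parsed (8 chars) by readers, so digitize against
    # the *rounded* physical limits actually stored
    pmin_stored = np.array([float(f"{phys_min[c]:.8g}"[:8]) for c in range(nch)])
    pmax_stored = np.array([float(f"{phys_max[c]:.8g}"[:8]) for c in range(nch)])
    scale = (dig_max - dig_min) / (pmax_stored - pmin_stored)
    dig = np.rint(
        (np.clip(signal, pmin_stored[:, None], pmax_stored[:, None]) - pmin_stored[:, None])
        * scale[:, None]
        + dig_min
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr)
        f.write(per)
        # data records: per record, channels back to back
        view = dig.reshape(nch, n_records, fs)
        for r in range(n_records):
            f.write(view[:, r, :].tobytes())


def read_edf_signal(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (signal_uV, labels, fs).

    Delegates parsing to MNE's EDF reader.  Values are converted back to
    microvolts; channel order is the file's own.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds EEG in volts
    return data, list(raw.ch_names), float(raw.info["sfreq"])


def read_record(
    edf_source: str | Path,
    annotations: Sequence[SeizureAnnotation] = (),
    *,
    subject_id: str = "",
    record_id: str | None = None,
    start_time_s: float = 0.0,
    channels: ChannelGroup | None = None,
) -> EEGRecord:
    """Read one EDF record restricted to the canonical channel group.

    The returned signal holds the file's raw samples unaltered (no
    filtering, artefact removal or rescaling), reordered to canonical
    channel order.  Extra channels are permitted and dropped; any missing
    canonical channel raises :class:`ChannelGroupMismatch`, mirroring the
    exclusion of off-montage records from analysis.
    """
    channels = channels or ChannelGroup()
    path = Path(edf_source)
    record_id = record_id if record_id is not None else path.name
    data, labels, fs = read_edf_signal(path)
    lut = {lab.strip().upper(): k for k, lab in enumerate(labels)}
    rows = []
    missing = []
    for lab in channels.labels:
        k = lut.get(lab.upper())
        if k is None:
            missing.append(lab)
        else:
            rows.append(k)
    if missing:
        raise ChannelGroupMismatch(
            f"{record_id}: missing canonical channels {missing}"
        )
    signal = data[rows]
    duration_s = signal.shape[1] / fs
    return EEGRecord(
        subject_id=subject_id,
        record_id=record_id,
        start_time_s=start_time_s,
        duration_s=duration_s,
        signal=signal,
        annotations=[a for a in annotations],
        fs=int(round(fs)),
        channels=channels,
    )


# ---------------------------------------------------------------------------
# Timelines and manifests
# ---------------------------------------------------------------------------


def build_timeline(records: Sequence[EEGRecord]) -> SubjectTimeline:
    """Assemble one subject's records into a sorted timeline.

    Sorting is by ``start_time_s``; the result is independent of input
    order.  Overlapping records raise :class:`ValidationError`.
    """
    if not records:
        raise ValidationError("cannot build a timeline from zero records")
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) != 1:
        raise ValidationError(f"records span multiple subjects: {sorted(subject_ids)}")
    return SubjectTimeline(subject_id=records[0].subject_id, records=list(records))


def load_subject(
    data_dir: str | Path,
    subject_id: str,
    *,
    strict: bool = False,
) -> tuple[SubjectTimeline, list[str]]:
    """Load one subject from ``<data_dir>/<subject_id>/`` (EDFs + summary).

    Expects ``<subject_id>-summary.txt`` next to the EDF files it names.
    Records whose EDF lacks the canonical channel group are excluded and
    returned in the second element (raised instead when ``strict``).
    """
    root = Path(data_dir) / subject_id
    summary_path = root / f"{subject_id}-summary.txt"
    entries = parse_summary(summary_path.read_text())
    records, excluded = [], []
    for record_id, start_time_s, _dur, anns in entries:
        try:
            records.append(
                read_record(
                    root / record_id,
                    anns,
                    subject_id=subject_id,
                    record_id=record_id,
                    start_time_s=start_time_s,
                )
            )
        except ChannelGroupMismatch:
            if strict:
                raise
            excluded.append(record_id)
    return build_timeline(records), excluded


def load_manifest(manifest_path: str | Path) -> list[tuple[str, Path]]:
    """Read a JSON manifest mapping subject ids to their data directory.

    Format: ``{"data_dir": "...", "subjects": ["chb01", ...]}`` with
    ``data_dir`` resolved relative to the manifest file.
    """
    p = Path(manifest_path)
    spec = json.loads(p.read_text())
    base = (p.parent / spec.get("data_dir", ".")).resolve()
    return [(s, base) for s in spec["subjects"]]
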