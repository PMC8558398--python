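"""Sensor EEG I/O and REMI montage construction.

A recording session uses four single-channel scalp sensors placed below the
hairline: left/right forehead (LF, RF, near F7/F8) and behind the left/right
ear (LE, RE, near T5/T6).  The four referential signals are combined with
their six pairwise differences into a fixed 10-channel montage, which is the
input to segmentation, feature extraction, and detection.

Signals travel as EDF/EDF+ files; annotations (seizure start/stop intervals
from ground truth, the algorithm, reviewers, or consensus) travel as CSV.
All times are seconds since a per-cohort epoch; intervals are half-open
``[start, stop)``.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import EDFFile, EDFSignalHeader, EPOCH, read_edf, write_edf

SENSOR_LABELS = ("LF", "RF", "LE", "RE")
#: Differential pairs in fixed lexicographic-pair order.
DIFFERENTIAL_PAIRS = (
    ("LF", "RF"), ("LF", "LE"), ("LF", "RE"),
    ("RF", "LE"), ("RF", "RE"), ("LE", "RE"),
)
MONTAGE_CHANNELS = SENSOR_LABELS + tuple(f"{a}-{b}" for a, b in DIFFERENTIAL_PAIRS)

DEFAULT_SAMPLING_RATE = 512.0
FULL_SCALE_UV = 175.0
PASSBAND_HZ = (0.8, 92.0)

ANNOTATION_COLUMNS = ["subject_id", "source", "start_s", "stop_s", "label"]


class MontageError(ValueError):
    """Missing/duplicated sensor placement or no temporal overlap."""


class UnitError(ValueError):
    """EDF signal recorded in units other than microvolts."""


class RangeError(ValueError):
    """Sample amplitudes exceed the sensor's full-scale range."""


class AnnotationError(ValueError):
    """Malformed annotation table."""


@dataclass
class SensorRecording:
    """One sensor's single-channel EEG trace.

    ``start_time`` is in seconds since the cohort epoch; ``samples`` are in
    microvolts at ``sampling_rate`` Hz.
    """

    sensor_label: str
    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    start_time: float = 0.0
    full_scale: float = FULL_SCALE_UV
    passband: tuple[float, float] = PASSBAND_HZ

    def __post_init__(self) -> None:
        if self.sensor_label not in SENSOR_LABELS:
            raise ValueError(
                f"sensor_label must be one of {SENSOR_LABELS}, "
                f"got {self.sensor_label!r}"
            )
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def stop_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class MontageRecording:
    """The 10-channel montage: 4 referential + 6 differential channels."""

    channels: np.ndarray          # shape (10, n_samples)
    sampling_rate: float
    start_time: float
    channel_names: tuple[str, ...] = MONTAGE_CHANNELS

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape[0] != len(self.channel_names):
            raise MontageError(
                f"expected {len(self.channel_names)} channels, "
                f"got {self.channels.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]


@dataclass(frozen=True)
class Event:
    start_s: float
    stop_s: float
    label: str = "seizure"

    def __post_init__(self) -> None:
        if not self.stop_s > self.start_s:
            raise AnnotationError(
                f"event stop ({self.stop_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class AnnotationSet:
    """A sorted list of timed events from one source.

    ``source`` is free-form but conventionally one of ``ground_truth``,
    ``algorithm``, ``reviewer_1..3``, ``consensus``.
    """

    source: str
    events: list[Event] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.stop_s))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def normalized(self) -> "AnnotationSet":
        """Merge overlapping/abutting events so the set is non-overlapping."""
        merged: list[Event] = []
        for ev in self.events:
            if merged and ev.start_s <= merged[-1].stop_s:
                last = merged[-1]
                merged[-1] = Event(
                    last.start_s, max(last.stop_s, ev.stop_s), last.label
                )
            else:
                merged.append(ev)
        return AnnotationSet(self.source, merged, self.subject_id)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of start/stop seconds."""
        if not self.events:
            return np.empty((0, 2))
        return np.array([[e.start_s, e.stop_s] for e in self.events])


# ---------------------------------------------------------------------------
# EDF I/O


def write_sensor_edf(rec: SensorRecording, path) -> Path:
    """Write one sensor recording as a single-signal EDF+ file.

    The physical range is the sensor's full scale (±175 μV by default); the
    digital range is the EDF-standard 16 bits.  Amplitudes outside full scale
    are a hard error — the hardware cannot produce them.
    """
    peak = float(np.max(np.abs(rec.samples))) if len(rec.samples) else 0.0
    if peak > rec.full_scale:
        raise RangeError(
            f"sample amplitude {peak:.3f} μV exceeds full scale "
            f"±{rec.full_scale} μV"
        )

    sr = rec.sampling_rate
    n = len(rec.samples)
    if n == 0:
        raise ValueError("cannot write an empty recording")
    # Whole seconds -> 1-s records; otherwise a single record holds everything.
    if sr == int(sr) and n % int(sr) == 0:
        record_duration, spr = 1.0, int(sr)
    else:
        record_duration, spr = n / sr, n

    hdr = EDFSignalHeader(
        label=f"EEG {rec.sensor_label}",
        dimension="uV",
        physical_min=-rec.full_scale,
        physical_max=rec.full_scale,
        # Symmetric digital range so 0 μV is exactly representable.
        digital_min=-32767,
        digital_max=32767,
        samples_per_record=spr,
        prefilter=f"HP:{rec.passband[0]}Hz LP:{rec.passband[1]}Hz",
    )
    start = EPOCH + _dt.timedelta(seconds=round(rec.start_time))
    edf = EDFFile(
        start=start,
        record_duration=record_duration,
        signal_headers=[hdr],
        signals=[rec.samples],
        recording_id=f"Startdate {start.strftime('%d-%b-%Y').upper()} X X X",
    )
    write_edf(path, edf)
    return Path(path)


_LABEL_RE = re.compile(r"\b(LF|RF|LE|RE)\b")


def read_sensor_edf(path) -> SensorRecording:
    """Read the first EEG signal of an EDF/EDF+ file as a SensorRecording.

    The sensor placement is parsed from the EDF signal label, falling back to
    the file name.  Signals in units other than microvolts are rejected.
    """
    edf = read_edf(path)
    hdr = edf.signal_headers[0]
    unit = hdr.dimension.strip()
    if unit not in ("uV", "µV"):
        raise UnitError(
            f"signal {hdr.label!r} has units {unit!r}; expected uV"
        )
    m = _LABEL_RE.search(hdr.label) or _LABEL_RE.search(Path(path).stem.upper())
    if m is None:
        raise MontageError(
            f"cannot determine sensor placement from label {hdr.label!r} "
            f"or file name {Path(path).name!r}"
        )
    sr = hdr.samples_per_record / edf.record_duration
    return SensorRecording(
        sensor_label=m.group(1),
        samples=edf.signals[0],
        sampling_rate=sr,
        start_time=edf.start_seconds,
        full_scale=max(abs(hdr.physical_min), abs(hdr.physical_max)),
    )


# ---------------------------------------------------------------------------
# Montage


def build_remi_montage(recs: list[SensorRecording]) -> MontageRecording:
    """Combine four sensor recordings into the fixed 10-channel montage.

    The four placements must each appear exactly once and share one sampling
    rate.  Channels are aligned by their start times and trimmed to the
    common temporal overlap; each differential channel ``A-B`` is the
    elementwise difference of referential channels A and B.
    """
    by_label = {}
    for rec in recs:
        if rec.sensor_label in by_label:
            raise MontageError(f"duplicated placement {rec.sensor_label}")
        by_label[rec.sensor_label] = rec
    missing = set(SENSOR_LABELS) - set(by_label)
    if missing:
        raise MontageError(f"missing placements: {sorted(missing)}")

    rates = {rec.sampling_rate for rec in recs}
    if len(rates) != 1:
        raise MontageError(f"sampling rates differ: {sorted(rates)}")
    sr = rates.pop()

    t0 = max(rec.start_time for rec in recs)
    t1 = min(rec.stop_time for rec in recs)
    if t1 <= t0:
        raise MontageError(
            f"no temporal overlap between sensors (overlap window "
            f"[{t0:.3f}, {t1:.3f}))"
        )
    n = int(round((t1 - t0) * sr))

    ref = {}
    for label, rec in by_label.items():
        i0 = int(round((t0 - rec.start_time) * sr))
        ref[label] = rec.samples[i0:i0 + n]

    channels = np.empty((10, n))
    for i, label in enumerate(SENSOR_LABELS):
        channels[i] = ref[label]
    for j, (a, b) in enumerate(DIFFERENTIAL_PAIRS):
        channels[4 + j] = ref[a] - ref[b]
    return MontageRecording(channels=channels, sampling_rate=sr, start_time=t0)


# ---------------------------------------------------------------------------
# Annotation CSV I/O


def write_annotations(annotations, path) -> Path:
    """Write one or more AnnotationSets to a CSV (header always present)."""
    if isinstance(annotations, AnnotationSet):
        annotations = [annotations]
    rows = [
        {
            "subject_id": ann.subject_id,
            "source": ann.source,
            "start_s": ev.start_s,
            "stop_s": ev.stop_s,
            "label": ev.label,
        }
        for ann in annotations
        for ev in ann.events
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "source": str, "label": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation CSV missing columns {sorted(missing)}")
    bad = df.index[df["stop_s"] <= df["start_s"]]
    if len(bad):
        row = df.loc[bad[0]]
        raise AnnotationError(
            f"row {bad[0]}: stop_s ({row['stop_s']}) <= start_s "
            f"({row['start_s']})"
        )
    return df


def read_annotations(path, subject_id: str | None = None,
                     source: str | None = None) -> AnnotationSet:
    """Read one AnnotationSet from a CSV, optionally filtered.

    If the file holds several subjects/sources, pass filters; the returned
    set takes its identity from the filters or from the (then necessarily
    unique) values in the file.
    """
    df = read_annotation_table(path)
    if subject_id is not None:
        df = df[df["subject_id"] == subject_id]
    if source is not None:
        df = df[df["source"] == source]
    subjects = df["subject_id"].unique()
    sources = df["source"].unique()
    if len(subjects) > 1 or len(sources) > 1:
        raise AnnotationError(
            "annotation CSV holds multiple subjects/sources; "
            "pass subject_id/source filters"
        )
    events = [
        Event(float(r.start_s), float(r.stop_s), str(r.label))
        for r in df.itertuples()
    ]
    return AnnotationSet(
        source=source or (sources[0] if len(sources) else "ground_truth"),
        events=events,
        subject_id=subject_id or (subjects[0] if len(subjects) else ""),
    )


def read_all_annotations(path) -> dict[tuple[str, str], AnnotationSet]:
    """Read a multi-subject/multi-source CSV into {(subject, source): set}."""
    df = read_annotation_table(path)
    out: dict[tuple[str, str], AnnotationSet] = {}
    for (subj, src), grp in df.groupby(["subject_id", "source"], sort=True):
        events = [
            Event(float(r.start_s), float(r.stop_s), str(r.label))
            for r in grp.itertuples()
        ]
        out[(subj, src)] = AnnotationSet(src, events, subj)
    return out
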