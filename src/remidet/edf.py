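"""Minimal EDF/EDF+ codec for single- and multi-signal continuous recordings.

Implements the subset of the European Data Format needed here: fixed-width
ASCII headers, int16 little-endian data records with linear physical/digital
scaling, and (for EDF+C) a time-keeping ``EDF Annotations`` signal holding one
timestamp TAL per record.  Only continuous recordings are supported.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np

#: Epoch against which all in-package times (seconds) are expressed.
EPOCH = _dt.datetime(2000, 1, 1, 0, 0, 0)

ANNOTATION_LABEL = "EDF Annotations"


class EDFFormatError(ValueError):
    """Raised when a file cannot be parsed as EDF/EDF+."""


@dataclass
class EDFSignalHeader:
    label: str
    dimension: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int
    transducer: str = ""
    prefilter: str = ""

    @property
    def gain(self) -> float:
        return (self.physical_max - self.physical_min) / (
            self.digital_max - self.digital_min
        )

    def digital_to_physical(self, digital: np.ndarray) -> np.ndarray:
        return (digital - self.digital_min) * self.gain + self.physical_min

    def physical_to_digital(self, physical: np.ndarray) -> np.ndarray:
        dig = np.round((physical - self.physical_min) / self.gain) + self.digital_min
        return dig.astype(np.int16)


@dataclass
class EDFFile:
    start: _dt.datetime
    record_duration: float
    signal_headers: list[EDFSignalHeader]
    signals: list[np.ndarray]          # physical units, one 1-D array per signal
    patient_id: str = "X X X X"
    recording_id: str = "Startdate X X X X"
    edfplus: bool = True
    n_records: int = 0

    @property
    def start_seconds(self) -> float:
        """Recording start as seconds since the package epoch."""
        return (self.start - EPOCH).total_seconds()


def _fw(value: str, width: int) -> bytes:
    """Fixed-width ASCII field, left-justified, space padded."""
    s = str(value)
    if len(s) > width:
        raise EDFFormatError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = repr(int(value)) if float(value).is_integer() else repr(float(value))
    if len(s) > width:
        s = f"{value:.{max(width - 7, 0)}g}"
    return _fw(s, width)


def write_edf(path, edf: EDFFile) -> None:
    """Write a continuous EDF (or EDF+C) file.

    Signals must each contain a whole number of records of
    ``samples_per_record`` samples at the declared record duration.
    """
    sig_headers = list(edf.signal_headers)
    signals = [np.asarray(s, dtype=float) for s in edf.signals]
    if len(sig_headers) != len(signals):
        raise EDFFormatError("signal/header count mismatch")

    n_records = None
    for hdr, sig in zip(sig_headers, signals):
        if sig.size % hdr.samples_per_record:
            raise EDFFormatError(
                f"signal {hdr.label!r}: {sig.size} samples not divisible by "
                f"samples_per_record={hdr.samples_per_record}"
            )
        nr = sig.size // hdr.samples_per_record
        if n_records is None:
            n_records = nr
        elif nr != n_records:
            raise EDFFormatError("signals disagree on record count")
    if n_records is None or n_records == 0:
        raise EDFFormatError("no signal data to write")

    if edf.edfplus:
        # Time-keeping annotations signal: one "+<onset>\x14\x14\x00" TAL per
        # record, sized to hold the longest onset string.
        longest = len(f"+{(n_records - 1) * edf.record_duration:g}") + 3
        ann_spr = math.ceil(longest / 2) + 1
        ann_hdr = EDFSignalHeader(
            label=ANNOTATION_LABEL, dimension="", physical_min=-1.0,
            physical_max=1.0, digital_min=-32768, digital_max=32767,
            samples_per_record=ann_spr,
        )
        sig_headers = sig_headers + [ann_hdr]

    ns = len(sig_headers)
    header_bytes = 256 * (1 + ns)

    buf = bytearray()
    buf += _fw("0", 8)
    buf += _fw(edf.patient_id, 80)
    buf += _fw(edf.recording_id, 80)
    buf += _fw(edf.start.strftime("%d.%m.%y"), 8)
    buf += _fw(edf.start.strftime("%H.%M.%S"), 8)
    buf += _fw(str(header_bytes), 8)
    buf += _fw("EDF+C" if edf.edfplus else "", 44)
    buf += _fw(str(n_records), 8)
    buf += _num(edf.record_duration, 8)
    buf += _fw(str(ns), 4)

    for get, width in (
        (lambda h: h.label, 16),
        (lambda h: h.transducer, 80),
        (lambda h: h.dimension, 8),
        (lambda h: _num_str(h.physical_min, 8), 8),
        (lambda h: _num_str(h.physical_max, 8), 8),
        (lambda h: str(h.digital_min), 8),
        (lambda h: str(h.digital_max), 8),
        (lambda h: h.prefilter, 80),
        (lambda h: str(h.samples_per_record), 8),
        (lambda h: "", 32),
    ):
        for hdr in sig_headers:
            buf += _fw(get(hdr), width)

    # Digitize once, then interleave record by record.
    digital = [
        hdr.physical_to_digital(sig)
        for hdr, sig in zip(sig_headers, signals)
    ]
    records = bytearray()
    for rec in range(n_records):
        for i, hdr in enumerate(sig_headers):
            if edf.edfplus and hdr.label == ANNOTATION_LABEL:
                tal = f"+{rec * edf.record_duration:g}\x14\x14\x00".encode("ascii")
                tal = tal.ljust(hdr.samples_per_record * 2, b"\x00")
                records += tal
            else:
                spr = hdr.samples_per_record
                chunk = digital[i][rec * spr:(rec + 1) * spr]
                records += chunk.astype("<i2").tobytes()

    with open(path, "wb") as fh:
        fh.write(bytes(buf))
        fh.write(bytes(records))


def _num_str(value: float, width: int) -> str:
    s = repr(int(value)) if float(value).is_integer() else repr(float(value))
    if len(s) > width:
        s = f"{value:.{max(width - 7, 0)}g}"
    return s


def _parse_ascii(raw: bytes, what: str) -> str:
    try:
        return raw.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise EDFFormatError(f"non-ASCII bytes in {what}") from exc


def read_edf(path) -> EDFFile:
    """Read a continuous EDF/EDF+ file; annotation signals are skipped."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError("file shorter than the 256-byte EDF header")
        version = _parse_ascii(head[0:8], "version")
        if version != "0":
            raise EDFFormatError(f"unsupported EDF version {version!r}")
        patient_id = _parse_ascii(head[8:88], "patient id")
        recording_id = _parse_ascii(head[88:168], "recording id")
        date_s = _parse_ascii(head[168:176], "start date")
        time_s = _parse_ascii(head[176:184], "start time")
        reserved = _parse_ascii(head[192:236], "reserved")
        try:
            n_records = int(_parse_ascii(head[236:244], "record count"))
            record_duration = float(_parse_ascii(head[244:252], "record duration"))
            ns = int(_parse_ascii(head[252:256], "signal count"))
        except ValueError as exc:
            raise EDFFormatError("malformed numeric header field") from exc
        if ns < 1:
            raise EDFFormatError("EDF file declares zero signals")
        try:
            start = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
        except ValueError as exc:
            raise EDFFormatError(f"bad start date/time {date_s!r} {time_s!r}") from exc

        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise EDFFormatError("truncated signal header block")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                _parse_ascii(sig_head[base + i * width: base + (i + 1) * width],
                             "signal header")
                for i in range(ns)
            ]

        labels = fields(0, 16)
        transducers = fields(16, 80)
        dims = fields(96, 8)
        try:
            pmins = [float(x) for x in fields(104, 8)]
            pmaxs = [float(x) for x in fields(112, 8)]
            dmins = [int(x) for x in fields(120, 8)]
            dmaxs = [int(x) for x in fields(128, 8)]
            prefilters = fields(136, 80)
            sprs = [int(x) for x in fields(216, 8)]
        except ValueError as exc:
            raise EDFFormatError("malformed signal header field") from exc

        headers = [
            EDFSignalHeader(
                label=labels[i], dimension=dims[i], physical_min=pmins[i],
                physical_max=pmaxs[i], digital_min=dmins[i],
                digital_max=dmaxs[i], samples_per_record=sprs[i],
                transducer=transducers[i], prefilter=prefilters[i],
            )
            for i in range(ns)
        ]

        rec_bytes = 2 * sum(sprs)
        data = fh.read(rec_bytes * n_records)
        if len(data) < rec_bytes * n_records:
            raise EDFFormatError("truncated data records")

    raw = np.frombuffer(data, dtype="<i2").reshape(n_records, sum(sprs))
    offsets = np.cumsum([0] + sprs)
    keep_headers: list[EDFSignalHeader] = []
    keep_signals: list[np.ndarray] = []
    for i, hdr in enumerate(headers):
        if hdr.label == ANNOTATION_LABEL:
            continue
        dig = raw[:, offsets[i]:offsets[i + 1]].reshape(-1).astype(float)
        keep_headers.append(hdr)
        keep_signals.append(hdr.digital_to_physical(dig))
    if not keep_headers:
        raise EDFFormatError("EDF file contains no data signals")

    return EDFFile(
        start=start,
        record_duration=record_duration,
        signal_headers=keep_headers,
        signals=keep_signals,
        patient_id=patient_id,
        recording_id=recording_id,
        edfplus=reserved.startswith("EDF+"),
        n_records=n_records,
    )
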