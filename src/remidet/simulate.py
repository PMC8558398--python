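"""Seeded synthetic EEG cohorts with ground-truth focal seizures.

The clinical recordings behind the detection pipeline are not publicly
deposited, so this module generates a sensor-realistic stand-in cohort:
four single-channel scalp sensors per subject (512 Hz, 10-bit over ±175 μV,
0.8–92 Hz passband), multi-hour stays, and focal-onset seizures injected as
evolving oscillations with largest gain on one onset sensor.

The background model is 1/f-weighted noise plus band-limited rhythmic
activity (a waxing-and-waning posterior-alpha surrogate) with a shared
common-source component across sensors as a crude volume-conduction
surrogate.  The ictal model is a frequency glide (8 → 3 Hz by default) with
a ramped envelope — the morphology is an invention chosen to be separable
from 1/f background by standard spectral/temporal features, not a calibrated
claim about recorded seizures.

Everything is deterministic given the cohort seed: per-subject and
per-purpose streams are derived by named-purpose fan-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._seeds import rng_for
from .io import (
    AnnotationSet,
    DEFAULT_SAMPLING_RATE,
    Event,
    FULL_SCALE_UV,
    PASSBAND_HZ,
    SENSOR_LABELS,
    SensorRecording,
)

#: Nominal background RMS in μV; ictal_snr is expressed relative to this.
BACKGROUND_RMS_UV = 15.0
#: 10-bit ADC grid over the ±175 μV full scale.
ADC_LEVELS = 1023

#: Relative gain of a seizure on non-onset sensors: same side of the head,
#: contralateral homologous site, and the diagonal site.
MIX_SAME_SIDE = 0.55
MIX_CONTRALATERAL = 0.40
MIX_DIAGONAL = 0.25

_SIDE = {"LF": "L", "RF": "R", "LE": "L", "RE": "R"}
_ROW = {"LF": "F", "RF": "F", "LE": "E", "RE": "E"}

MIN_SEIZURE_S = 10.0
MAX_SEIZURE_S = 900.0
#: Minimum separation between consecutive seizure onsets (s).
MIN_ONSET_GAP_S = 1800.0
#: Minimum distance of any seizure from the record edges (s); chosen one
#: near-ictal margin plus one minute so labelled windows never leave the
#: record.
EDGE_MARGIN_S = 960.0


class PlacementError(RuntimeError):
    """Stay too short to place the requested seizures."""


@dataclass
class CohortSpec:
    """Stated world of a synthetic cohort.

    Defaults mirror the study cohort structure (20 subjects, half with
    focal-onset seizures, 1–6 per subject with mean ≈ 2.4) at scaled-down
    stays of 2–6 h; multi-day stays are available by configuration.
    """

    n_subjects: int = 20
    n_with_seizures: int = 10
    #: Probability over seizure counts 1..6 (mean ≈ 2.45, median 2).
    seizures_per_subject: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.35, 3: 0.15, 4: 0.10, 6: 0.10}
    )
    stay_hours: tuple[float, float] = (2.0, 6.0)
    seizure_duration_s: tuple[float, float] = (30.0, 300.0)
    ictal_snr: float = 4.0
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.n_with_seizures <= self.n_subjects:
            raise ValueError("need 0 <= n_with_seizures <= n_subjects")
        lo, hi = self.seizure_duration_s
        if not (MIN_SEIZURE_S <= lo <= hi <= MAX_SEIZURE_S):
            raise ValueError(
                f"seizure_duration_s must lie within "
                f"[{MIN_SEIZURE_S}, {MAX_SEIZURE_S}] s"
            )
        if self.ictal_snr < 0:
            raise ValueError("ictal_snr must be non-negative")
        total = sum(self.seizures_per_subject.values())
        if not np.isclose(total, 1.0):
            raise ValueError("seizures_per_subject probabilities must sum to 1")
        if any(not 1 <= k <= 6 for k in self.seizures_per_subject):
            raise ValueError("seizure counts must lie in 1..6")


@dataclass
class SubjectRecord:
    subject_id: str
    sensors: list[SensorRecording]
    ground_truth: AnnotationSet
    has_seizures: bool

    @property
    def record_hours(self) -> float:
        return self.sensors[0].duration / 3600.0


def _quantize(x: np.ndarray, full_scale: float = FULL_SCALE_UV) -> np.ndarray:
    """Clip to full scale and snap to the 10-bit ADC amplitude grid."""
    step = 2.0 * full_scale / ADC_LEVELS
    return np.clip(np.round(x / step) * step, -full_scale, full_scale)


def _bandpass_sos(sampling_rate: float):
    lo, hi = PASSBAND_HZ
    hi = min(hi, 0.45 * sampling_rate)      # keep the edge below Nyquist
    return sps.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate,
                      output="sos")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-weighted Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    weight = np.zeros_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * weight, n)
    return shaped / shaped.std()


def generate_background(duration_s: float,
                        sampling_rate: float = DEFAULT_SAMPLING_RATE,
                        seed: int = 0,
                        rms_uv: float = BACKGROUND_RMS_UV,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate one sensor's background EEG (μV).

    1/f noise plus an amplitude-modulated ~10 Hz rhythm, band-pass filtered
    to the 0.8–92 Hz amplifier passband, scaled to ``rms_uv``, then clipped
    and quantized to the 10-bit grid over ±175 μV.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate

    x = _pink_noise(n, rng)
    # Waxing/waning alpha-band rhythm, ~30% of background power.
    alpha_f = rng.uniform(9.0, 11.0)
    mod = 0.5 * (1.0 + np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t
                              + rng.uniform(0, 2 * np.pi)))
    x = x + 0.8 * mod * np.sin(2 * np.pi * alpha_f * t
                               + rng.uniform(0, 2 * np.pi))

    x = sps.sosfiltfilt(_bandpass_sos(sampling_rate), x)
    x = x * (rms_uv / np.std(x))
    return _quantize(x)


def generate_seizure_waveform(duration_s: float,
                              onset_sensor: str,
                              ictal_snr: float,
                              seed: int = 0,
                              sampling_rate: float = DEFAULT_SAMPLING_RATE,
                              f_start: float = 8.0,
                              f_stop: float = 3.0,
                              rng: np.random.Generator | None = None
                              ) -> np.ndarray:
    """Additive ictal waveform for the four sensors, shape (4, n).

    An evolving oscillation — frequency gliding ``f_start`` → ``f_stop`` Hz
    with a ramp-up/ramp-down envelope and a weak second harmonic — scaled so
    the onset-sensor RMS is ``ictal_snr`` × the nominal background RMS, and
    mixed onto the other sensors with fixed sub-unity gains.  Output rows
    follow :data:`remidet.io.SENSOR_LABELS` order.
    """
    if not MIN_SEIZURE_S <= duration_s <= MAX_SEIZURE_S:
        raise ValueError(
            f"duration_s must lie in [{MIN_SEIZURE_S}, {MAX_SEIZURE_S}] s"
        )
    if onset_sensor not in SENSOR_LABELS:
        raise ValueError(f"onset_sensor must be one of {SENSOR_LABELS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate

    freq = f_start + (f_stop - f_start) * (t / duration_s)
    phase = 2 * np.pi * np.cumsum(freq) / sampling_rate
    carrier = np.sin(phase) + 0.25 * np.sin(2 * phase + rng.uniform(0, 2 * np.pi))

    ramp = min(duration_s * 0.2, 10.0)
    env = np.minimum(1.0, np.minimum(t / ramp, (duration_s - t) / ramp))
    env = np.clip(env, 0.0, 1.0)
    # Slow seeded amplitude waxing, multiplicative so RMS stays linear in snr.
    wax = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t
                             + rng.uniform(0, 2 * np.pi))
    base = carrier * env * wax

    rms = np.sqrt(np.mean(base**2))
    if rms > 0:
        base = base / rms
    onset_wave = base * (ictal_snr * BACKGROUND_RMS_UV)

    out = np.zeros((len(SENSOR_LABELS), n))
    for i, label in enumerate(SENSOR_LABELS):
        if label == onset_sensor:
            gain = 1.0
        elif _SIDE[label] == _SIDE[onset_sensor]:
            gain = MIX_SAME_SIDE
        elif _ROW[label] == _ROW[onset_sensor]:
            gain = MIX_CONTRALATERAL
        else:
            gain = MIX_DIAGONAL
        out[i] = gain * onset_wave
    return out


def _place_onsets(rng: np.random.Generator, stay_s: float, durations:
                  np.ndarray, max_tries: int = 1000) -> np.ndarray:
    """Uniform onset placement under edge-margin and onset-gap constraints."""
    k = len(durations)
    if k == 0:
        return np.empty(0)
    for _ in range(max_tries):
        hi = stay_s - EDGE_MARGIN_S - durations
        if np.any(hi <= EDGE_MARGIN_S):
            break
        onsets = np.sort(rng.uniform(EDGE_MARGIN_S, hi))
        if k == 1 or np.all(np.diff(onsets) > MIN_ONSET_GAP_S):
            return onsets
    raise PlacementError(
        f"cannot place {k} seizures (durations up to "
        f"{durations.max():.0f} s) in a {stay_s / 3600:.2f}-h stay with "
        f"{MIN_ONSET_GAP_S:.0f}-s onset gaps and {EDGE_MARGIN_S:.0f}-s edge "
        f"margins"
    )


def generate_subject(spec: CohortSpec, subject_id: str,
                     with_seizures: bool, seed: int | None = None
                     ) -> SubjectRecord:
    """Generate one subject: four sensor recordings plus ground truth.

    ``seed`` defaults to a stream derived from ``spec.seed`` and the subject
    id, so cohort-level and single-subject generation agree.
    """
    if seed is None:
        seed = spec.seed
    rng_stay = rng_for(seed, "subject", subject_id, "stay")
    stay_s = float(np.round(rng_stay.uniform(*spec.stay_hours) * 3600.0))
    sr = spec.sampling_rate
    n = int(round(stay_s * sr))

    events: list[Event] = []
    additive = np.zeros((len(SENSOR_LABELS), n))
    if with_seizures:
        rng_sz = rng_for(seed, "subject", subject_id, "seizures")
        counts = sorted(spec.seizures_per_subject)
        probs = [spec.seizures_per_subject[c] for c in counts]
        k = int(rng_sz.choice(counts, p=probs))
        # A short stay cannot host an arbitrary seizure count: truncate the
        # draw to what fits under the edge-margin and onset-gap rules, and
        # fail only when not even one seizure fits.
        max_dur = spec.seizure_duration_s[1]
        width = stay_s - 2 * EDGE_MARGIN_S - max_dur
        k_max = 0 if width < 0 else 1 + int(width // MIN_ONSET_GAP_S)
        if k_max == 0:
            raise PlacementError(
                f"a {stay_s / 3600:.2f}-h stay cannot host any seizure with "
                f"{EDGE_MARGIN_S:.0f}-s edge margins and durations up to "
                f"{max_dur:.0f} s"
            )
        k = min(k, k_max)
        durations = rng_sz.uniform(*spec.seizure_duration_s, size=k)
        onsets = _place_onsets(rng_sz, stay_s, durations)
        for onset, dur in zip(onsets, durations):
            onset_sensor = str(rng_sz.choice(SENSOR_LABELS))
            wave = generate_seizure_waveform(
                dur, onset_sensor, spec.ictal_snr,
                sampling_rate=sr, rng=rng_sz,
            )
            i0 = int(round(onset * sr))
            i1 = i0 + wave.shape[1]
            additive[:, i0:i1] += wave
            events.append(Event(onset, onset + dur, f"focal_{onset_sensor}"))

    # Shared common-source background plus per-sensor background.
    rng_common = rng_for(seed, "subject", subject_id, "background", "common")
    common = generate_background(stay_s, sr, rng=rng_common)
    sensors = []
    for i, label in enumerate(SENSOR_LABELS):
        rng_bg = rng_for(seed, "subject", subject_id, "background", label)
        own = generate_background(stay_s, sr, rng=rng_bg)
        mixed = 0.9 * own + 0.45 * common + additive[i]
        sensors.append(
            SensorRecording(
                sensor_label=label,
                samples=_quantize(mixed),
                sampling_rate=sr,
                start_time=0.0,
            )
        )

    truth = AnnotationSet("ground_truth", events, subject_id)
    return SubjectRecord(subject_id, sensors, truth, with_seizures)


def subject_ids(spec: CohortSpec) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(spec.n_subjects)]


def seizure_flags(spec: CohortSpec) -> dict[str, bool]:
    """Which subjects carry seizures: the first ``n_with_seizures`` ids."""
    ids = subject_ids(spec)
    return {sid: i < spec.n_with_seizures for i, sid in enumerate(ids)}


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort in memory.

    For long stays or many subjects prefer iterating
    :func:`generate_subject` and discarding signals after use; a cohort of
    multi-hour 512-Hz recordings is large.
    """
    flags = seizure_flags(spec)
    return [
        generate_subject(spec, sid, with_seizures=flags[sid], seed=spec.seed)
        for sid in subject_ids(spec)
    ]


def simulate_reviewer_marks(truth: AnnotationSet,
                            hit_rate: float,
                            fp_per_hour: float,
                            boundary_jitter_s: float,
                            record_hours: float,
                            seed: int = 0,
                            source: str = "reviewer") -> AnnotationSet:
    """Simulate one reviewer's seizure marks from ground truth.

    Each truth event is reproduced independently with probability
    ``hit_rate`` and its boundaries jittered by ±``boundary_jitter_s``;
    Poisson(``fp_per_hour`` × ``record_hours``) spurious marks are placed
    away from truth events.
    """
    if not 0.0 <= hit_rate <= 1.0:
        raise ValueError("hit_rate must lie in [0, 1]")
    if fp_per_hour < 0 or boundary_jitter_s < 0 or record_hours <= 0:
        raise ValueError("rates/jitter must be non-negative, hours positive")
    rng = np.random.default_rng(seed)
    record_s = record_hours * 3600.0

    marks: list[Event] = []
    for ev in truth:
        if rng.uniform() >= hit_rate:
            continue
        start = ev.start_s + rng.uniform(-boundary_jitter_s, boundary_jitter_s)
        stop = ev.stop_s + rng.uniform(-boundary_jitter_s, boundary_jitter_s)
        start = max(0.0, start)
        stop = min(record_s, max(stop, start + 1.0))
        marks.append(Event(start, stop, ev.label))

    n_fp = rng.poisson(fp_per_hour * record_hours)
    intervals = truth.intervals()
    placed = 0
    tries = 0
    while placed < n_fp and tries < 100 * max(n_fp, 1):
        tries += 1
        dur = rng.uniform(20.0, 120.0)
        start = rng.uniform(0.0, max(record_s - dur, 1.0))
        stop = start + dur
        # Keep spurious marks clear of true events (60-s guard band).
        if len(intervals) and np.any(
            (start < intervals[:, 1] + 60.0) & (stop > intervals[:, 0] - 60.0)
        ):
            continue
        marks.append(Event(start, stop, "false_mark"))
        placed += 1

    return AnnotationSet(source, marks, truth.subject_id).normalized()
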