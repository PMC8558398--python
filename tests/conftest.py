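"""Shared fixtures: small deterministic montages and a reusable cohort."""

from __future__ import annotations

import numpy as np
import pytest

from remidet.io import SENSOR_LABELS, MontageRecording, SensorRecording, build_remi_montage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_sensors(samples_by_label: dict[str, np.ndarray],
                 sampling_rate: float = 512.0,
                 start_time: float = 0.0) -> list[SensorRecording]:
    return [
        SensorRecording(lab, samples_by_label[lab], sampling_rate, start_time)
        for lab in SENSOR_LABELS
    ]


def noise_montage(rng, duration_s: float = 10.0,
                  sampling_rate: float = 512.0,
                  scale: float = 10.0) -> MontageRecording:
    n = int(duration_s * sampling_rate)
    recs = make_sensors(
        {lab: rng.normal(0.0, scale, n) for lab in SENSOR_LABELS},
        sampling_rate,
    )
    return build_remi_montage(recs)


@pytest.fixture
def small_montage(rng):
    """10-s white-noise montage at 512 Hz."""
    return noise_montage(rng)
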