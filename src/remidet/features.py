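"""Segmentation, segment scoring, and per-segment feature extraction.

The 10-channel montage is cut into non-overlapping 2-s windows.  Each window
is scored ``ictal`` (overlaps a known seizure by any amount), ``near_ictal``
(within 15 min of a seizure boundary) or ``non_ictal``, and a fixed-schema
feature vector is computed across four domains:

* time: variance, line length, RMS;
* frequency: absolute and relative band power (delta/theta/alpha/beta/gamma)
  from a Hann-windowed periodogram;
* time-frequency: multilevel discrete-wavelet (db4) energies;
* complexity: spectral entropy and sample entropy.

Seizures evolve over time, so each per-channel feature is augmented with an
exponentially weighted history of its past values; cross-channel structure
is captured by across-channel summary statistics per feature plus the six
zero-lag sensor-pair correlations per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import (
    AnnotationSet,
    DIFFERENTIAL_PAIRS,
    MontageRecording,
    PASSBAND_HZ,
)

NEAR_ICTAL_MARGIN_S = 900.0

ICTAL, NEAR_ICTAL, NON_ICTAL = "ictal", "near_ictal", "non_ictal"

DEFAULT_BANDS = {
    "delta": (0.8, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
}

# db4 decomposition low-pass filter (8 taps).
_DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
_DB4_HI = np.array([(-1.0) ** k * c for k, c in enumerate(_DB4_LO[::-1])])


class TooShortError(ValueError):
    """Recording shorter than one analysis window."""


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentGrid:
    """Non-overlapping, contiguous analysis windows (trailing partial dropped)."""

    start_time: float
    n_segments: int
    window_s: float = 2.0
    hop_s: float = 2.0

    def bounds(self) -> np.ndarray:
        """(n, 2) array of absolute [start, stop) seconds per segment."""
        starts = self.start_time + np.arange(self.n_segments) * self.hop_s
        return np.column_stack([starts, starts + self.window_s])

    @property
    def duration(self) -> float:
        return self.n_segments * self.hop_s


@dataclass
class FeatureConfig:
    band_edges_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    wavelet_levels: int = 5
    sampen_embedding: int = 2
    sampen_tolerance: float = 0.2       # × segment SD
    #: Pooling factor before sample entropy (512 Hz → 64 Hz, 128 points/2 s),
    #: keeping the O(n²) template match tractable at cohort scale.
    sampen_pool: int = 8
    history_decay: float = 0.8          # α_h; ~10-segment memory

    def __post_init__(self) -> None:
        lo, hi = PASSBAND_HZ
        for name, (b0, b1) in self.band_edges_hz.items():
            if not (lo <= b0 < b1 <= hi):
                raise ConfigError(
                    f"band {name} ({b0}-{b1} Hz) outside passband {lo}-{hi} Hz"
                )
        if not 0.0 < self.history_decay < 1.0:
            raise ConfigError("history_decay must lie in (0, 1)")
        if self.wavelet_levels < 1:
            raise ConfigError("wavelet_levels must be >= 1")


@dataclass
class LabeledFeatureSet:
    """Per-segment feature matrix with segment labels for one subject."""

    subject_id: str
    X: np.ndarray                   # (n_segments, n_features)
    feature_names: list[str]
    labels: np.ndarray              # (n_segments,) of ictal/near_ictal/non_ictal
    grid: SegmentGrid
    record_hours: float

    def __post_init__(self) -> None:
        if self.X.shape != (self.grid.n_segments, len(self.feature_names)):
            raise ValueError("feature matrix shape does not match grid/names")
        if len(self.labels) != self.grid.n_segments:
            raise ValueError("label count does not match grid")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")


def segment(m: MontageRecording, window_s: float = 2.0) -> SegmentGrid:
    """Cut the montage into non-overlapping windows; partial tail dropped."""
    n = int(np.floor(m.duration / window_s))
    if n < 1:
        raise TooShortError(
            f"recording of {m.duration:.2f} s is shorter than one "
            f"{window_s}-s window"
        )
    return SegmentGrid(start_time=m.start_time, n_segments=n,
                       window_s=window_s, hop_s=window_s)


def label_segments(grid: SegmentGrid, truth: AnnotationSet,
                   margin_s: float = NEAR_ICTAL_MARGIN_S) -> np.ndarray:
    """Score each segment ictal / near-ictal / non-ictal against truth.

    A segment is ictal if it overlaps any truth event by any positive
    amount, near-ictal if it lies within ``margin_s`` (15 min) before or
    after a truth event, and non-ictal otherwise.
    """
    bounds = grid.bounds()
    labels = np.full(grid.n_segments, NON_ICTAL, dtype="<U10")
    ivals = truth.intervals()
    if len(ivals) == 0:
        return labels
    s0, s1 = bounds[:, 0:1], bounds[:, 1:2]
    ev0, ev1 = ivals[:, 0], ivals[:, 1]
    ictal = ((s0 < ev1) & (s1 > ev0)).any(axis=1)
    near = ((s0 < ev1 + margin_s) & (s1 > ev0 - margin_s)).any(axis=1)
    labels[near] = NEAR_ICTAL
    labels[ictal] = ICTAL
    return labels


# ---------------------------------------------------------------------------
# Per-channel features


def _dwt_energies(segs: np.ndarray, levels: int) -> np.ndarray:
    """Mean-square detail energies per level plus final approximation.

    A causal db4 analysis pyramid (filter + dyadic decimation) applied along
    the last axis; adequate for energy features, where boundary handling is
    immaterial.
    """
    out = np.empty(segs.shape[:-1] + (levels + 1,))
    approx = segs
    for lv in range(levels):
        detail = sps.lfilter(_DB4_HI, [1.0], approx, axis=-1)[..., ::2]
        approx = sps.lfilter(_DB4_LO, [1.0], approx, axis=-1)[..., ::2]
        out[..., lv] = np.mean(detail**2, axis=-1)
    out[..., levels] = np.mean(approx**2, axis=-1)
    return out


def _sample_entropy(segs: np.ndarray, m: int, r_factor: float,
                    pool: int, chunk: int = 256) -> np.ndarray:
    """Sample entropy per segment (rows), on mean-pooled samples.

    SampEn(m, r) = −ln(A/B) with template matches counted Richman–Moorman
    style under the Chebyshev distance, r = ``r_factor`` × SD per segment.
    Degenerate segments (zero SD or no length-m matches) return 0 by
    convention; A = 0 is capped at one match so the value stays finite.
    """
    n_seg, win = segs.shape
    nd = win // pool
    x = segs[:, :nd * pool].reshape(n_seg, nd, pool).mean(axis=2)
    sd = x.std(axis=1)
    out = np.zeros(n_seg)
    n_templates = nd - m
    for lo in range(0, n_seg, chunk):
        xs = x[lo:lo + chunk]
        r = (r_factor * sd[lo:lo + chunk])[:, None, None]
        d0 = np.abs(xs[:, :, None] - xs[:, None, :])
        dm = d0[:, :n_templates, :n_templates]
        for k in range(1, m):
            dm = np.maximum(dm, d0[:, k:k + n_templates, k:k + n_templates])
        dm1 = np.maximum(dm, d0[:, m:m + n_templates, m:m + n_templates])
        B = (dm < r).sum(axis=(1, 2)) - n_templates      # drop self-matches
        A = (dm1 < r).sum(axis=(1, 2)) - n_templates
        valid = (sd[lo:lo + chunk] > 0) & (B > 0)
        ratio = np.where(valid, np.maximum(A, 1) / np.maximum(B, 1), 1.0)
        out[lo:lo + chunk] = np.where(valid, -np.log(ratio), 0.0)
    return out


def channel_feature_names(cfg: FeatureConfig) -> list[str]:
    names = ["var", "line_length", "rms"]
    names += [f"bp_{b}" for b in cfg.band_edges_hz]
    names += [f"rbp_{b}" for b in cfg.band_edges_hz]
    names += [f"wav_d{i + 1}" for i in range(cfg.wavelet_levels)]
    names += [f"wav_a{cfg.wavelet_levels}"]
    names += ["spec_entropy", "samp_entropy"]
    return names


def _channel_features(segs: np.ndarray, sr: float,
                      cfg: FeatureConfig) -> np.ndarray:
    """Feature block for one channel; ``segs`` is (n_segments, win)."""
    n_seg = segs.shape[0]
    cols: list[np.ndarray] = []

    cols.append(segs.var(axis=1))
    cols.append(np.abs(np.diff(segs, axis=1)).sum(axis=1))
    cols.append(np.sqrt(np.mean(segs**2, axis=1)))

    freqs, psd = sps.periodogram(segs, fs=sr, window="hann", axis=1)
    df = freqs[1] - freqs[0]
    pb = (freqs >= PASSBAND_HZ[0]) & (freqs <= PASSBAND_HZ[1])
    total = psd[:, pb].sum(axis=1) * df
    band_abs = []
    for b0, b1 in cfg.band_edges_hz.values():
        mask = (freqs >= b0) & (freqs < b1)
        band_abs.append(psd[:, mask].sum(axis=1) * df)
    cols.extend(band_abs)
    safe_total = np.where(total > 0, total, 1.0)
    for p in band_abs:
        cols.append(np.where(total > 0, p / safe_total, 0.0))

    cols.extend(_dwt_energies(segs, cfg.wavelet_levels).T)

    # Spectral entropy over the passband, normalized to [0, 1].
    p_pb = psd[:, pb]
    norm = p_pb.sum(axis=1, keepdims=True)
    prob = np.where(norm > 0, p_pb / np.where(norm > 0, norm, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(prob > 0, prob * np.log(prob), 0.0)
    spec_ent = np.where(
        norm[:, 0] > 0, -plogp.sum(axis=1) / np.log(p_pb.shape[1]), 0.0
    )
    cols.append(spec_ent)

    cols.append(
        _sample_entropy(segs, cfg.sampen_embedding, cfg.sampen_tolerance,
                        cfg.sampen_pool)
    )
    return np.column_stack(cols) if n_seg else np.empty((0, len(cols)))


def extract_segment_features(m: MontageRecording, grid: SegmentGrid,
                             cfg: FeatureConfig | None = None
                             ) -> tuple[np.ndarray, list[str]]:
    """Per-channel features for every segment.

    Returns ``(X, names)`` with one block of
    :func:`channel_feature_names` per montage channel, in montage channel
    order.
    """
    cfg = cfg or FeatureConfig()
    win = int(round(grid.window_s * m.sampling_rate))
    n_used = grid.n_segments * win
    base_names = channel_feature_names(cfg)
    blocks, names = [], []
    for ch_name, ch in zip(m.channel_names, m.channels):
        segs = ch[:n_used].reshape(grid.n_segments, win)
        blocks.append(_channel_features(segs, m.sampling_rate, cfg))
        names.extend(f"{ch_name}|{b}" for b in base_names)
    return np.hstack(blocks), names


def add_history(X: np.ndarray, names: list[str],
                alpha: float) -> tuple[np.ndarray, list[str]]:
    """Append an exponentially weighted history column per feature.

    ``h_t = α·h_{t−1} + (1−α)·f_t`` with ``h_0 = f_0``; rows must be in
    temporal order.  Doubles the feature count.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("history decay must lie in (0, 1)")
    hist = np.empty_like(X)
    if len(X):
        hist[0] = X[0]
        for t in range(1, len(X)):
            hist[t] = alpha * hist[t - 1] + (1.0 - alpha) * X[t]
    return np.hstack([X, hist]), names + [f"{n}|hist" for n in names]


def add_cross_channel(X: np.ndarray, names: list[str],
                      m: MontageRecording, grid: SegmentGrid,
                      cfg: FeatureConfig | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """Append cross-channel summaries and sensor-pair correlations.

    Per base feature: mean, SD, max, min of its 10 per-channel values.  Per
    segment: the six zero-lag Pearson correlations of the broadband
    sensor-pair signals; a zero-variance channel yields correlation 0 by
    convention.
    """
    cfg = cfg or FeatureConfig()
    base = channel_feature_names(cfg)
    n_ch = len(m.channel_names)
    cols, new_names = [], []
    for j, feat in enumerate(base):
        idx = [names.index(f"{ch}|{feat}") for ch in m.channel_names]
        block = X[:, idx]
        for stat, fn in (("mean", np.mean), ("std", np.std),
                         ("max", np.max), ("min", np.min)):
            cols.append(fn(block, axis=1))
            new_names.append(f"xch_{stat}|{feat}")
    del n_ch

    win = int(round(grid.window_s * m.sampling_rate))
    n_used = grid.n_segments * win
    segs = {
        lab: m.channel(lab)[:n_used].reshape(grid.n_segments, win)
        for lab in ("LF", "RF", "LE", "RE")
    }
    centered = {lab: s - s.mean(axis=1, keepdims=True)
                for lab, s in segs.items()}
    sd = {lab: s.std(axis=1) for lab, s in segs.items()}
    for a, b in DIFFERENTIAL_PAIRS:
        denom = sd[a] * sd[b] * win
        cov = (centered[a] * centered[b]).sum(axis=1)
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        cols.append(corr)
        new_names.append(f"corr|{a}-{b}")

    return np.hstack([X, np.column_stack(cols)]), names + new_names


def featurize(m: MontageRecording, truth: AnnotationSet,
              cfg: FeatureConfig | None = None,
              subject_id: str = "") -> LabeledFeatureSet:
    """Full feature pipeline for one subject's montage."""
    cfg = cfg or FeatureConfig()
    grid = segment(m)
    labels = label_segments(grid, truth)
    X, names = extract_segment_features(m, grid, cfg)
    X, names = add_history(X, names, cfg.history_decay)
    X, names = add_cross_channel(X, names, m, grid, cfg)
    return LabeledFeatureSet(
        subject_id=subject_id or truth.subject_id,
        X=X, feature_names=names, labels=labels, grid=grid,
        record_hours=m.duration / 3600.0,
    )
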