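"""Segment classifier, likelihood integration, and event formation.

Training follows a leave-one-subject-out scheme: for each held-out subject a
random forest (500 trees, bootstrapped, grown to full splits) is trained on
the remaining subjects' ictal and non-ictal segments, with the non-ictal
class randomly subsampled to a 3:1 non-ictal:ictal ratio and near-ictal
segments excluded from training entirely.  The per-segment ictal likelihood
is smoothed with a first-order leaky integrator, and whole-seizure events
are formed by a run-length threshold rule: five continuous supra-threshold
segments (10 s) open an event, five continuous sub-threshold segments close
it.  Events closer than 2 min are merged, and merged events longer than
15 min are discarded.  The detection threshold is calibrated on the
training subjects to reach at least 90% event-level sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter as sps_lfilter
from sklearn.ensemble import RandomForestClassifier

from ._seeds import int_seed, rng_for
from .evaluation import match_events
from .features import ICTAL, NEAR_ICTAL, NON_ICTAL, LabeledFeatureSet, SegmentGrid
from .io import AnnotationSet, Event

N_TREES = 500
BALANCE_RATIO = 3.0
TRIGGER_RUN = 5
MERGE_GAP_S = 120.0
MAX_EVENT_S = 900.0
TARGET_TRAIN_SENSITIVITY = 0.90


class TrainingError(RuntimeError):
    pass


class FeatureSchemaError(ValueError):
    pass


@dataclass
class TrainingSet:
    X: np.ndarray
    y: np.ndarray                  # 1 = ictal, 0 = non-ictal
    feature_names: list[str]
    provenance: list[str]          # subject ids included
    #: (subject_id, segment index) per training row, for OOB trace repair.
    row_origin: list[tuple[str, int]] = field(default_factory=list)
    balance_ratio: float = BALANCE_RATIO
    seed: int = 0

    @property
    def n_ictal(self) -> int:
        return int(self.y.sum())

    @property
    def n_non_ictal(self) -> int:
        return int((self.y == 0).sum())


@dataclass
class DetectorModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    seed: int = 0


@dataclass
class IntegratorConfig:
    """Leaky-integrator and event-formation parameters.

    ``alpha`` is the integrator leak; ``threshold`` the fixed detection
    threshold (calibrated when None); run/merge/discard constants follow the
    published post-processing rules.
    """

    alpha: float = 0.8
    threshold: float | None = None
    trigger_run: int = TRIGGER_RUN
    merge_gap_s: float = MERGE_GAP_S
    max_event_s: float = MAX_EVENT_S
    threshold_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 0.951, 0.01), 2)
    )
    target_sensitivity: float = TARGET_TRAIN_SENSITIVITY

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("integrator alpha must lie in (0, 1)")
        if self.trigger_run < 1:
            raise ValueError("trigger_run must be >= 1")
        if self.merge_gap_s <= 0 or self.max_event_s <= 0:
            raise ValueError("merge_gap_s and max_event_s must be positive")

    @property
    def latency_segments(self) -> int:
        """Integrator group delay in segments, L = round(α/(1−α))."""
        return int(round(self.alpha / (1.0 - self.alpha)))


@dataclass(frozen=True)
class DetectionEvent:
    start_s: float
    stop_s: float
    peak_likelihood: float = 0.0

    def __post_init__(self) -> None:
        if not self.stop_s > self.start_s:
            raise ValueError("detection stop must exceed start")

    @property
    def duration(self) -> float:
        return self.stop_s - self.start_s


def events_to_annotations(events: list[DetectionEvent], subject_id: str = "",
                          source: str = "algorithm") -> AnnotationSet:
    return AnnotationSet(
        source,
        [Event(e.start_s, e.stop_s, "detection") for e in events],
        subject_id,
    )


# ---------------------------------------------------------------------------
# Training


def assemble_training(feature_sets: list[LabeledFeatureSet],
                      held_out: str | None, seed: int = 0) -> TrainingSet:
    """Pool ictal/non-ictal segments from all subjects except ``held_out``.

    All ictal rows are kept; non-ictal rows are subsampled without
    replacement to a 3:1 non-ictal:ictal ratio (or all kept if fewer are
    available).  Near-ictal rows never enter training.
    """
    included = [fs for fs in feature_sets if fs.subject_id != held_out]
    if len(feature_sets) < 2 or not included:
        raise TrainingError("need at least two subjects for LOSO training")
    names = included[0].feature_names
    for fs in included:
        if fs.feature_names != names:
            raise FeatureSchemaError(
                f"feature schema of subject {fs.subject_id} differs"
            )

    X_ict, ict_origin = [], []
    X_non, non_origin = [], []
    for fs in included:
        ict_idx = np.flatnonzero(fs.labels == ICTAL)
        non_idx = np.flatnonzero(fs.labels == NON_ICTAL)
        X_ict.append(fs.X[ict_idx])
        X_non.append(fs.X[non_idx])
        ict_origin += [(fs.subject_id, int(i)) for i in ict_idx]
        non_origin += [(fs.subject_id, int(i)) for i in non_idx]
    X_ict = np.vstack(X_ict)
    X_non = np.vstack(X_non)
    if len(X_ict) == 0:
        raise TrainingError("no ictal segments in the training pool")

    n_keep = min(int(BALANCE_RATIO * len(X_ict)), len(X_non))
    rng = rng_for(seed, "training-balance", held_out or "")
    keep = rng.choice(len(X_non), size=n_keep, replace=False)
    keep.sort()
    X = np.vstack([X_ict, X_non[keep]])
    y = np.concatenate([np.ones(len(X_ict), dtype=int),
                        np.zeros(n_keep, dtype=int)])
    origin = ict_origin + [non_origin[i] for i in keep]
    return TrainingSet(
        X=X, y=y, feature_names=list(names),
        provenance=[fs.subject_id for fs in included],
        row_origin=origin, seed=seed,
    )


def train(ts: TrainingSet, seed: int = 0) -> DetectorModel:
    """Fit the 500-tree random forest (bootstrap on, unlimited depth)."""
    if len(np.unique(ts.y)) < 2:
        raise TrainingError("training set must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=N_TREES,
        bootstrap=True,
        max_depth=None,
        random_state=int_seed(seed, "forest", *ts.provenance),
        n_jobs=1,
    )
    forest.fit(ts.X, ts.y)
    return DetectorModel(forest=forest, feature_names=list(ts.feature_names),
                         seed=seed)


def score(model: DetectorModel, fs: LabeledFeatureSet) -> np.ndarray:
    """Ictal class likelihood per segment, in temporal order."""
    if fs.feature_names != model.feature_names:
        missing = sorted(set(model.feature_names) - set(fs.feature_names))
        if missing:
            raise FeatureSchemaError(f"missing features: {missing[:5]} ...")
        # Same names, different order: re-align by name.
        order = [fs.feature_names.index(n) for n in model.feature_names]
        X = fs.X[:, order]
    else:
        X = fs.X
    ictal_col = int(np.flatnonzero(model.forest.classes_ == 1)[0])
    return model.forest.predict_proba(X)[:, ictal_col]


def oob_likelihoods(model: DetectorModel, ts: TrainingSet) -> np.ndarray:
    """Out-of-bag ictal likelihood for every training row.

    In-sample forest likelihoods saturate near 0/1 for rows the trees were
    grown on, which would let any threshold pass a training-sensitivity
    check.  Averaging each row's prediction over only the trees that did not
    bootstrap it gives an honest estimate of out-of-sample behaviour.  Rows
    never left out of bag (vanishingly rare at 500 trees) fall back to the
    in-sample likelihood.
    """
    forest = model.forest
    n = len(ts.X)
    ictal_col = int(np.flatnonzero(forest.classes_ == 1)[0])
    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        if not oob_mask.any():
            continue
        proba = tree.predict_proba(ts.X[oob_mask])[:, ictal_col]
        sums[oob_mask] += proba
        counts[oob_mask] += 1
    fallback = forest.predict_proba(ts.X)[:, ictal_col]
    return np.where(counts > 0, sums / np.maximum(counts, 1), fallback)


def calibration_traces(model: DetectorModel, ts: TrainingSet,
                       train_sets: list[LabeledFeatureSet],
                       alpha: float) -> list[np.ndarray]:
    """Integrated likelihood traces of the training subjects for calibration.

    Segments that entered the training matrix are scored out-of-bag; all
    other segments (near-ictal and unsampled non-ictal) are ordinary
    out-of-sample predictions.
    """
    oob = oob_likelihoods(model, ts)
    by_subject: dict[str, dict[int, float]] = {}
    for (sid, seg), val in zip(ts.row_origin, oob):
        by_subject.setdefault(sid, {})[seg] = float(val)
    traces = []
    for fs in train_sets:
        p = score(model, fs)
        for seg, val in by_subject.get(fs.subject_id, {}).items():
            p[seg] = val
        traces.append(integrate(p, alpha))
    return traces


# ---------------------------------------------------------------------------
# Integration and event formation


def integrate(p: np.ndarray, alpha: float) -> np.ndarray:
    """Leaky weighted integrator: y_t = α·y_{t−1} + (1−α)·p_t, y₋₁ = 0."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("integrator alpha must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    return sps_lfilter([1.0 - alpha], [1.0, -alpha], p)


def detect_events(y: np.ndarray, cfg: IntegratorConfig,
                  grid: SegmentGrid) -> list[DetectionEvent]:
    """Form seizure events from the integrated likelihood trace.

    A start marker is set once the trace exceeds the threshold for
    ``trigger_run`` continuous segments; the start time is the start of the
    first supra-threshold segment shifted earlier by the integrator latency
    (L = round(α/(1−α)) segments, floored at the record start).  A stop
    marker is set once the trace falls below threshold for ``trigger_run``
    continuous segments; the stop time is the end of the last
    supra-threshold segment.  An event still open at the record end is
    closed at the record end.
    """
    if cfg.threshold is None:
        raise ValueError("cfg.threshold is unset; calibrate first")
    y = np.asarray(y, dtype=float)
    if len(y) != grid.n_segments:
        raise ValueError("trace length does not match segment grid")
    above = y > cfg.threshold
    bounds = grid.bounds()
    latency_s = cfg.latency_segments * grid.hop_s

    events: list[DetectionEvent] = []
    run = cfg.trigger_run
    in_event = False
    i = 0
    n = len(y)
    start_s = 0.0
    start_i = 0
    last_above = -1
    while i < n:
        if not in_event:
            if above[i] and i + run <= n and above[i:i + run].all():
                raw = bounds[i, 0] - latency_s
                start_s = max(raw, grid.start_time)
                in_event = True
                start_i = i
                last_above = i
                i += run
            else:
                i += 1
        else:
            if above[i]:
                last_above = i
                i += 1
            elif i + run <= n and not above[i:i + run].any():
                stop_s = bounds[last_above, 1]
                peak = float(y[start_i:last_above + 1].max())
                events.append(DetectionEvent(start_s, stop_s, peak))
                in_event = False
                i += run
            else:
                i += 1
    if in_event:
        stop_s = bounds[-1, 1]          # open at record end: close there
        peak = float(y[start_i:].max())
        events.append(DetectionEvent(start_s, stop_s, peak))
    return events


def postprocess(events: list[DetectionEvent],
                cfg: IntegratorConfig | None = None) -> list[DetectionEvent]:
    """Merge events closer than 2 min, then discard events longer than 15 min.

    Merging is iterated to a fixed point before any discarding, so a chain
    of nearby short events can grow past the duration cap and be removed as
    a whole.
    """
    cfg = cfg or IntegratorConfig()
    merged: list[DetectionEvent] = []
    for ev in sorted(events, key=lambda e: e.start_s):
        if merged and ev.start_s - merged[-1].stop_s < cfg.merge_gap_s:
            last = merged[-1]
            merged[-1] = DetectionEvent(
                last.start_s, max(last.stop_s, ev.stop_s),
                max(last.peak_likelihood, ev.peak_likelihood),
            )
        else:
            merged.append(ev)
    return [ev for ev in merged if ev.duration <= cfg.max_event_s]


# ---------------------------------------------------------------------------
# Threshold calibration and LOSO orchestration


def _event_sensitivity(truths: list[AnnotationSet],
                       detections: list[AnnotationSet]) -> float:
    """Pooled any-overlap event sensitivity over subjects; 1.0 if no truths."""
    tp = fn = 0
    for truth, det in zip(truths, detections):
        res = match_events(truth, det)
        tp += len(res.tp_events)
        fn += len(res.fn_events)
    return tp / (tp + fn) if tp + fn else 1.0


def detections_at_threshold(traces: list[np.ndarray],
                            grids: list[SegmentGrid],
                            cfg: IntegratorConfig,
                            theta: float,
                            subject_ids: list[str] | None = None
                            ) -> list[AnnotationSet]:
    """Detect + post-process every trace at one threshold."""
    c = replace(cfg, threshold=float(theta))
    ids = subject_ids or [""] * len(traces)
    return [
        events_to_annotations(postprocess(detect_events(y, c, g), c), sid)
        for y, g, sid in zip(traces, grids, ids)
    ]


def calibrate_threshold(traces: list[np.ndarray],
                        grids: list[SegmentGrid],
                        truths: list[AnnotationSet],
                        cfg: IntegratorConfig | None = None) -> float:
    """Largest threshold reaching the target training sensitivity.

    Sweeps the candidate grid from high to low, evaluating event-level
    any-overlap sensitivity after post-processing on the training subjects;
    returns the largest θ with sensitivity ≥ target (≥90% by default).  If
    no candidate qualifies, returns the grid minimum with a warning.
    """
    cfg = cfg or IntegratorConfig()
    grid_vals = np.sort(np.asarray(cfg.threshold_grid, dtype=float))[::-1]
    if grid_vals.size == 0:
        raise ValueError("empty threshold candidate grid")
    if not any(len(t) for t in truths):
        raise TrainingError("no truth events among training subjects")
    for theta in grid_vals:
        dets = detections_at_threshold(traces, grids, cfg, theta)
        if _event_sensitivity(truths, dets) >= cfg.target_sensitivity:
            return float(theta)
    warnings.warn(
        "no threshold reached the target training sensitivity; "
        "falling back to the grid minimum", RuntimeWarning,
    )
    return float(grid_vals[-1])


@dataclass
class SubjectDetections:
    subject_id: str
    events: list[DetectionEvent]
    likelihood: np.ndarray
    integrated: np.ndarray
    threshold: float
    grid: SegmentGrid

    def annotations(self) -> AnnotationSet:
        return events_to_annotations(self.events, self.subject_id)


def run_loso(feature_sets: list[LabeledFeatureSet],
             truths: dict[str, AnnotationSet],
             cfg: IntegratorConfig | None = None,
             seed: int = 0) -> dict[str, SubjectDetections]:
    """Leave-one-subject-out detection over a featurized cohort.

    For each subject: train a balanced forest on all other subjects,
    calibrate the threshold on those training subjects' own integrated
    traces, then score/integrate/detect/post-process the held-out subject's
    complete feature set (near-ictal segments included).
    """
    cfg = cfg or IntegratorConfig()
    if len(feature_sets) < 2:
        raise TrainingError("LOSO requires at least two subjects")
    results: dict[str, SubjectDetections] = {}
    for fs in feature_sets:
        held = fs.subject_id
        ts = assemble_training(feature_sets, held_out=held, seed=seed)
        model = train(ts, seed=seed)

        if cfg.threshold is None:
            train_sets = [f for f in feature_sets if f.subject_id != held]
            train_traces = calibration_traces(model, ts, train_sets,
                                              cfg.alpha)
            theta = calibrate_threshold(
                train_traces, [f.grid for f in train_sets],
                [truths[f.subject_id] for f in train_sets], cfg,
            )
        else:
            theta = cfg.threshold

        p = score(model, fs)
        y = integrate(p, cfg.alpha)
        events = postprocess(
            detect_events(y, replace(cfg, threshold=theta), fs.grid), cfg
        )
        results[held] = SubjectDetections(
            subject_id=held, events=events, likelihood=p, integrated=y,
            threshold=theta, grid=fs.grid,
        )
    return results
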