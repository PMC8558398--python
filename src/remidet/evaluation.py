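"""Any-overlap event scoring, cohort summaries, consensus, and kappa.

Event-level scoring uses the any-overlap rule: a known seizure is a true
positive if at least one detection overlaps it by any positive amount, and
a detection is a false positive if it overlaps no known seizure.  One
detection may validate several seizures and one seizure may be validated by
several detections (the standard OVLP reading); a detection is never both
matched and a false positive.  For true positives, percent overlap is the
fraction of the known seizure's duration covered by the union of its
matched detections.

Reviewer agreement over the known seizure events is summarized by Cohen's
kappa for rater pairs and Fleiss' kappa for the group, with a 2-of-3
majority consensus built by 1-s pointwise voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import AnnotationSet, Event


@dataclass
class MatchResult:
    """Any-overlap bookkeeping for one subject."""

    tp_events: list[Event]                  # truth events with >=1 match
    fn_events: list[Event]                  # truth events with no match
    fp_detections: list[Event]              # detections matching no truth
    matched_detections: dict[int, list[Event]]   # truth index -> detections
    overlap_pct: dict[int, float]           # truth index -> percent overlap

    @property
    def n_tp(self) -> int:
        return len(self.tp_events)

    @property
    def n_fn(self) -> int:
        return len(self.fn_events)

    @property
    def n_fp(self) -> int:
        return len(self.fp_detections)


@dataclass
class SubjectMetrics:
    subject_id: str
    sensitivity: float | None       # %, None when the subject has no truths
    precision: float | None         # %
    fdr: float                      # false positives per hour
    record_hours: float
    n_truth: int
    n_detections: int
    mean_overlap: float | None      # %, over this subject's TPs


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def match_events(truth: AnnotationSet, detected: AnnotationSet) -> MatchResult:
    """Score detections against truth with the any-overlap rule."""
    tps, fns = [], []
    matched: dict[int, list[Event]] = {}
    overlap_pct: dict[int, float] = {}
    det_matched = [False] * len(detected.events)

    for i, tr in enumerate(truth.events):
        hits = []
        for j, de in enumerate(detected.events):
            if _overlap(tr.start_s, tr.stop_s, de.start_s, de.stop_s) > 0:
                hits.append(de)
                det_matched[j] = True
        if hits:
            tps.append(tr)
            matched[i] = hits
            overlap_pct[i] = percent_overlap(tr, hits)
        else:
            fns.append(tr)

    fps = [de for j, de in enumerate(detected.events) if not det_matched[j]]
    return MatchResult(tps, fns, fps, matched, overlap_pct)


def percent_overlap(truth_event: Event, detections: list[Event]) -> float:
    """Percent of the known seizure covered by the union of detections."""
    clipped = [
        (max(d.start_s, truth_event.start_s), min(d.stop_s, truth_event.stop_s))
        for d in detections
        if _overlap(truth_event.start_s, truth_event.stop_s,
                    d.start_s, d.stop_s) > 0
    ]
    if not clipped:
        raise ValueError("no detection overlaps the truth event")
    clipped.sort()
    covered = 0.0
    cur0, cur1 = clipped[0]
    for s0, s1 in clipped[1:]:
        if s0 > cur1:
            covered += cur1 - cur0
            cur0, cur1 = s0, s1
        else:
            cur1 = max(cur1, s1)
    covered += cur1 - cur0
    return 100.0 * covered / truth_event.duration


def subject_metrics(match: MatchResult, record_hours: float,
                    subject_id: str = "") -> SubjectMetrics:
    """Per-subject sensitivity (%), precision (%), and FDR (FP/h).

    Sensitivity is undefined (None) for subjects without truth events.
    Precision is 100 when there are neither detections nor truths, and
    computable (0) when detections exist without truths.
    """
    if record_hours <= 0:
        raise ValueError("record_hours must be positive")
    tp, fn, fp = match.n_tp, match.n_fn, match.n_fp
    n_truth = tp + fn
    matched_unique = {
        (d.start_s, d.stop_s)
        for hits in match.matched_detections.values() for d in hits
    }
    n_det = fp + len(matched_unique)
    sensitivity = 100.0 * tp / n_truth if n_truth else None
    if tp + fp:
        precision = 100.0 * tp / (tp + fp)
    else:
        # No TPs and no FPs: perfect (100) when nothing was there to find,
        # undefined when seizures existed but nothing was detected.
        precision = 100.0 if n_truth == 0 else None
    overlaps = list(match.overlap_pct.values())
    return SubjectMetrics(
        subject_id=subject_id,
        sensitivity=sensitivity,
        precision=precision,
        fdr=fp / record_hours,
        record_hours=record_hours,
        n_truth=n_truth,
        n_detections=n_det,
        mean_overlap=float(np.mean(overlaps)) if overlaps else None,
    )


def cohort_summary(metrics: list[SubjectMetrics]) -> pd.DataFrame:
    """Across-subject mean ± SD and range per metric.

    Subjects with an undefined value are excluded from that metric's
    summary (a subject with no seizures contributes no sensitivity).
    """
    if not metrics:
        raise ValueError("no subjects to summarize")
    rows = []
    for name in ("sensitivity", "precision", "fdr", "mean_overlap"):
        vals = [getattr(m, name) for m in metrics]
        vals = np.array([v for v in vals if v is not None], dtype=float)
        if vals.size == 0:
            rows.append({"metric": name, "n": 0, "mean": np.nan,
                         "sd": np.nan, "min": np.nan, "max": np.nan})
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({
            "metric": name, "n": int(vals.size), "mean": float(vals.mean()),
            "sd": sd, "min": float(vals.min()), "max": float(vals.max()),
        })
    return pd.DataFrame(rows).set_index("metric")


def rule_in_metrics(matches: dict[str, MatchResult],
                    has_seizures: dict[str, bool]) -> tuple[float, float]:
    """Patient-level (sensitivity %, specificity %).

    Sensitivity: fraction of seizure subjects with at least one true
    positive.  Specificity: fraction of seizure-free subjects with zero
    detections of any kind.
    """
    pos = [sid for sid, f in has_seizures.items() if f]
    neg = [sid for sid, f in has_seizures.items() if not f]
    sens = (
        100.0 * sum(matches[s].n_tp > 0 for s in pos) / len(pos)
        if pos else float("nan")
    )
    spec = (
        100.0 * sum(matches[s].n_fp == 0 and matches[s].n_tp == 0
                    for s in neg) / len(neg)
        if neg else float("nan")
    )
    return sens, spec


# ---------------------------------------------------------------------------
# Consensus and inter-rater agreement


def consensus(mark_sets: list[AnnotationSet], resolution_s: float = 1.0,
              min_duration_s: float = 2.0) -> AnnotationSet:
    """2-of-3 majority consensus by pointwise voting.

    Each reviewer's events are rasterized at ``resolution_s``; time points
    marked by at least two of the three reviewers form the consensus, and
    contiguous runs shorter than ``min_duration_s`` are discarded.
    """
    if len(mark_sets) != 3:
        raise ValueError("consensus requires exactly 3 mark sets")
    stop = max((ev.stop_s for ms in mark_sets for ev in ms), default=0.0)
    n = int(np.ceil(stop / resolution_s)) + 1
    votes = np.zeros(n, dtype=int)
    edges = np.arange(n) * resolution_s
    for ms in mark_sets:
        marked = np.zeros(n, dtype=bool)
        for ev in ms:
            i0 = int(np.floor(ev.start_s / resolution_s))
            i1 = int(np.ceil(ev.stop_s / resolution_s))
            marked[i0:i1] = True
        votes += marked

    keep = votes >= 2
    events = []
    i = 0
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            start, end = edges[i], edges[i] + (j - i) * resolution_s
            if end - start >= min_duration_s:
                events.append(Event(start, end, "consensus"))
            i = j
        else:
            i += 1
    subject = mark_sets[0].subject_id
    return AnnotationSet("consensus", events, subject)


def build_rater_table(truth: AnnotationSet,
                      rater_marks: list[AnnotationSet]) -> np.ndarray:
    """Known-seizure × rater binary table (1 = rater overlapped the event)."""
    table = np.zeros((len(truth.events), len(rater_marks)), dtype=int)
    for i, tr in enumerate(truth.events):
        for j, marks in enumerate(rater_marks):
            table[i, j] = int(any(
                _overlap(tr.start_s, tr.stop_s, m.start_s, m.stop_s) > 0
                for m in marks
            ))
    return table


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's κ for two binary raters over the same items.

    κ = (p_o − p_e)/(1 − p_e); if both observed and chance agreement are 1
    (degenerate unanimity) κ is defined as 1.0.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("raters must be equal-length non-empty 1-D vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("rater tables must be binary")
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = float(
        np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b))
    )
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' κ for a fixed group of binary raters.

    ``table`` is items × raters with binary cells.  A degenerate table where
    every rating falls in one category returns 1.0 by convention.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("need an items × raters table with >= 2 raters")
    if not np.isin(table, (0, 1)).all():
        raise ValueError("rater tables must be binary")
    n_items, n_raters = table.shape
    counts = np.column_stack([
        (table == 0).sum(axis=1), (table == 1).sum(axis=1)
    ])
    p_j = counts.sum(axis=0) / (n_items * n_raters)
    P_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    P_bar = P_i.mean()
    P_e = float((p_j**2).sum())
    if np.isclose(P_e, 1.0):
        return 1.0 if np.isclose(P_bar, 1.0) else 0.0
    return float((P_bar - P_e) / (1.0 - P_e))


def pairwise_kappas(table: np.ndarray) -> dict[tuple[int, int], float]:
    """Cohen's κ for every rater pair of an items × raters table."""
    table = np.asarray(table)
    return {
        (i, j): cohens_kappa(table[:, i], table[:, j])
        for i, j in combinations(range(table.shape[1]), 2)
    }
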