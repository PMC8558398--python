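"""Training-set assembly, forest training, integration, event formation."""

import numpy as np
import pytest

from remidet.detector import (
    IntegratorConfig,
    TrainingError,
    assemble_training,
    calibrate_threshold,
    detect_events,
    detections_at_threshold,
    integrate,
    postprocess,
    run_loso,
    score,
    train,
    DetectionEvent,
)
from remidet.evaluation import match_events
from remidet.features import ICTAL, NEAR_ICTAL, NON_ICTAL, LabeledFeatureSet, SegmentGrid
from remidet.io import AnnotationSet, Event


def toy_feature_set(subject_id: str, labels: list[str], seed: int = 0,
                    separation: float = 8.0) -> LabeledFeatureSet:
    """Two-cluster features: ictal rows shifted by ``separation``."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    X = rng.normal(0.0, 1.0, size=(len(labels), 4))
    X[labels == ICTAL] += separation
    grid = SegmentGrid(start_time=0.0, n_segments=len(labels))
    return LabeledFeatureSet(
        subject_id=subject_id, X=X,
        feature_names=[f"f{i}" for i in range(4)],
        labels=labels, grid=grid,
        record_hours=grid.duration / 3600.0,
    )


def labels_with_event(n: int, ictal_slice: slice) -> list[str]:
    labels = [NON_ICTAL] * n
    for i in range(*ictal_slice.indices(n)):
        labels[i] = ICTAL
    return labels


class TestAssembleTraining:
    def _sets(self, n_ictal, n_non, extra_near=5):
        labels = ([ICTAL] * n_ictal + [NON_ICTAL] * n_non
                  + [NEAR_ICTAL] * extra_near)
        return [
            toy_feature_set("A", labels, seed=1),
            toy_feature_set("B", labels_with_event(50, slice(0, 0)), seed=2),
        ]

    def test_three_to_one_balance(self):
        ts = assemble_training(self._sets(40, 1000), held_out=None, seed=0)
        assert ts.n_ictal == 40
        assert ts.n_non_ictal == 120

    def test_shortfall_keeps_all_non_ictal(self):
        ts = assemble_training(self._sets(40, 40), held_out=None, seed=0)
        assert ts.n_ictal == 40
        assert ts.n_non_ictal == 40 + 50            # subject B adds 50

    def test_held_out_subject_excluded(self):
        sets = self._sets(20, 200)
        ts = assemble_training(sets, held_out="B", seed=0)
        assert ts.provenance == ["A"]

    def test_near_ictal_never_enters_training(self):
        sets = self._sets(10, 30, extra_near=500)
        ts = assemble_training(sets, held_out=None, seed=0)
        assert len(ts.y) == ts.n_ictal + ts.n_non_ictal <= 10 + 30 + 50

    def test_no_ictal_rows_raises(self):
        sets = [
            toy_feature_set("A", [NON_ICTAL] * 30, seed=1),
            toy_feature_set("B", [NON_ICTAL] * 30, seed=2),
        ]
        with pytest.raises(TrainingError):
            assemble_training(sets, held_out=None, seed=0)

    def test_subsampling_seeded(self):
        sets = self._sets(10, 500)
        a = assemble_training(sets, held_out=None, seed=3)
        b = assemble_training(sets, held_out=None, seed=3)
        np.testing.assert_array_equal(a.X, b.X)


class TestForest:
    def _trained(self):
        labels = labels_with_event(200, slice(0, 40))
        fs = toy_feature_set("A", labels, seed=5)
        other = toy_feature_set("B", labels, seed=6)
        ts = assemble_training([fs, other], held_out="B", seed=0)
        return train(ts, seed=0), fs, ts

    def test_separable_clusters_scored_confidently(self):
        model, fs, ts = self._trained()
        p = score(model, fs)
        assert p.shape == (200,)
        assert np.all((0.0 <= p) & (p <= 1.0))
        assert np.all(p[fs.labels == ICTAL] > 0.5)
        assert np.all(p[fs.labels == NON_ICTAL] < 0.5)

    def test_same_seed_identical_predictions(self):
        model1, fs, ts = self._trained()
        model2 = train(ts, seed=0)
        np.testing.assert_array_equal(score(model1, fs), score(model2, fs))

    def test_forest_shape_matches_contract(self):
        model, _, _ = self._trained()
        assert model.forest.n_estimators == 500
        assert model.forest.bootstrap is True
        assert model.forest.max_depth is None

    def test_single_class_training_rejected(self):
        fs = toy_feature_set("A", [ICTAL] * 10 + [NON_ICTAL] * 5)
        ts = assemble_training([fs, toy_feature_set("B", [NON_ICTAL] * 5)],
                               held_out=None, seed=0)
        ts.y[:] = 1
        with pytest.raises(TrainingError):
            train(ts, seed=0)

    def test_column_permutation_with_names_is_invariant(self):
        model, fs, _ = self._trained()
        perm = [2, 0, 3, 1]
        shuffled = LabeledFeatureSet(
            subject_id=fs.subject_id, X=fs.X[:, perm],
            feature_names=[fs.feature_names[i] for i in perm],
            labels=fs.labels, grid=fs.grid, record_hours=fs.record_hours,
        )
        np.testing.assert_array_equal(score(model, fs),
                                      score(model, shuffled))


class TestIntegrator:
    def test_zero_input_zero_output(self):
        np.testing.assert_array_equal(integrate(np.zeros(10), 0.8),
                                      np.zeros(10))

    def test_constant_input_converges_from_below(self):
        y = integrate(np.full(60, 0.7), 0.8)
        assert np.all(np.diff(y) > 0)
        assert y[-1] < 0.7
        assert y[-1] == pytest.approx(0.7, abs=1e-4)

    def test_hand_recursion(self):
        np.testing.assert_allclose(integrate(np.ones(3), 0.5),
                                   [0.5, 0.75, 0.875])

    def test_bounded_by_input_supremum(self, rng):
        p = rng.uniform(size=500)
        y = integrate(p, 0.9)
        assert y.max() <= p.max() + 1e-12
        assert y.min() >= 0.0

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -1.0])
    def test_alpha_validation(self, alpha):
        with pytest.raises(ValueError):
            integrate(np.zeros(3), alpha)


class TestDetectEvents:
    def cfg(self, threshold=0.5, alpha=0.5):
        return IntegratorConfig(alpha=alpha, threshold=threshold)

    def grid(self, n):
        return SegmentGrid(start_time=0.0, n_segments=n)

    def test_sub_threshold_trace_yields_no_events(self):
        y = np.full(50, 0.2)
        assert detect_events(y, self.cfg(), self.grid(50)) == []

    def test_four_segment_run_insufficient(self):
        y = np.zeros(30)
        y[10:14] = 0.9                              # only 4 segments
        assert detect_events(y, self.cfg(), self.grid(30)) == []

    def test_hand_worked_marker_rules(self):
        # α = 0.5 → latency L = 1 segment (2 s). Supra-threshold segments
        # 10–19 → start = 20 s − 2 s = 18 s, stop = end of segment 19 = 40 s.
        y = np.zeros(30)
        y[10:20] = 0.9
        events = detect_events(y, self.cfg(), self.grid(30))
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(18.0)
        assert events[0].stop_s == pytest.approx(40.0)

    def test_latency_correction_floors_at_record_start(self):
        y = np.zeros(20)
        y[0:6] = 0.9
        events = detect_events(y, self.cfg(alpha=0.9), self.grid(20))
        assert events[0].start_s == 0.0

    def test_short_dip_does_not_close_event(self):
        y = np.zeros(60)
        y[10:20] = 0.9
        y[22:30] = 0.9                              # 2-segment dip only
        events = detect_events(y, self.cfg(), self.grid(60))
        assert len(events) == 1
        assert events[0].stop_s == pytest.approx(60.0)

    def test_open_event_closed_at_record_end(self):
        y = np.zeros(20)
        y[12:] = 0.9
        events = detect_events(y, self.cfg(), self.grid(20))
        assert len(events) == 1
        assert events[0].stop_s == pytest.approx(40.0)

    def test_unset_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(10), IntegratorConfig(), self.grid(10))


class TestPostprocess:
    def test_nearby_events_merge(self):
        events = [DetectionEvent(0, 30), DetectionEvent(90, 120)]
        out = postprocess(events)
        assert [(e.start_s, e.stop_s) for e in out] == [(0, 120)]

    def test_merge_is_iterative(self):
        events = [DetectionEvent(0, 30), DetectionEvent(100, 130),
                  DetectionEvent(200, 230)]
        out = postprocess(events)
        assert [(e.start_s, e.stop_s) for e in out] == [(0, 230)]

    def test_long_merged_event_discarded(self):
        events = [DetectionEvent(0, 500), DetectionEvent(560, 960)]
        assert postprocess(events) == []            # 16 min after merge

    def test_discard_only_after_merge(self):
        # Two 8-min events 1 min apart merge to 17 min, then vanish.
        events = [DetectionEvent(0, 480), DetectionEvent(540, 1020)]
        assert postprocess(events) == []

    def test_empty_input(self):
        assert postprocess([]) == []

    def test_gap_of_exactly_two_minutes_not_merged(self):
        events = [DetectionEvent(0, 30), DetectionEvent(150, 180)]
        out = postprocess(events)
        assert len(out) == 2


class TestCalibration:
    def _traces(self, n_subj=3, n=400, sep_quality=1.0):
        grids, traces, truths = [], [], []
        for s in range(n_subj):
            grid = SegmentGrid(start_time=0.0, n_segments=n)
            y = np.full(n, 0.02)
            ev_start, ev_stop = 100 + 10 * s, 130 + 10 * s
            y[ev_start:ev_stop] = sep_quality
            grids.append(grid)
            traces.append(y)
            truths.append(AnnotationSet("gt", [
                Event(2.0 * ev_start, 2.0 * ev_stop)
            ], f"S{s}"))
        return traces, grids, truths

    def test_perfect_traces_pick_largest_threshold(self):
        traces, grids, truths = self._traces(sep_quality=1.0)
        cfg = IntegratorConfig()
        theta = calibrate_threshold(traces, grids, truths, cfg)
        assert theta == pytest.approx(cfg.threshold_grid.max())

    def test_sensitivity_at_threshold_meets_target(self):
        traces, grids, truths = self._traces(sep_quality=0.6)
        cfg = IntegratorConfig()
        theta = calibrate_threshold(traces, grids, truths, cfg)
        dets = detections_at_threshold(traces, grids, cfg, theta)
        tp = sum(match_events(t, d).n_tp for t, d in zip(truths, dets))
        total = sum(len(t) for t in truths)
        assert tp / total >= 0.90

    def test_sensitivity_monotone_in_threshold(self):
        traces, grids, truths = self._traces(sep_quality=0.55)
        cfg = IntegratorConfig()
        sens = []
        for theta in np.arange(0.05, 0.95, 0.05):
            dets = detections_at_threshold(traces, grids, cfg, theta)
            tp = sum(match_events(t, d).n_tp for t, d in zip(truths, dets))
            sens.append(tp / sum(len(t) for t in truths))
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_no_truth_events_rejected(self):
        traces, grids, _ = self._traces()
        empties = [AnnotationSet("gt", []) for _ in traces]
        with pytest.raises(TrainingError):
            calibrate_threshold(traces, grids, empties)

    def test_empty_grid_rejected(self):
        traces, grids, truths = self._traces()
        cfg = IntegratorConfig(threshold_grid=np.array([]))
        with pytest.raises(ValueError):
            calibrate_threshold(traces, grids, truths, cfg)

    def test_unreachable_target_warns_and_returns_minimum(self):
        grids = [SegmentGrid(start_time=0.0, n_segments=50)]
        traces = [np.zeros(50)]
        truths = [AnnotationSet("gt", [Event(10.0, 20.0)])]
        with pytest.warns(RuntimeWarning):
            theta = calibrate_threshold(traces, grids, truths)
        assert theta == pytest.approx(0.05)


class TestRunLoso:
    def _cohort(self):
        sets = []
        for s, seed in zip("ABC", (1, 2, 3)):
            labels = labels_with_event(300, slice(100, 115))
            sets.append(toy_feature_set(s, labels, seed=seed))
        truths = {
            fs.subject_id: AnnotationSet(
                "gt", [Event(200.0, 230.0)], fs.subject_id
            )
            for fs in sets
        }
        return sets, truths

    def test_loso_produces_per_subject_events(self):
        sets, truths = self._cohort()
        results = run_loso(sets, truths, seed=0)
        assert set(results) == {"A", "B", "C"}
        for sid, det in results.items():
            assert det.subject_id == sid
            match = match_events(truths[sid], det.annotations())
            assert match.n_tp == 1                  # separable by design
            assert len(det.likelihood) == 300

    def test_loso_deterministic(self):
        sets, truths = self._cohort()
        r1 = run_loso(sets, truths, seed=7)
        r2 = run_loso(sets, truths, seed=7)
        for sid in r1:
            np.testing.assert_array_equal(r1[sid].integrated,
                                          r2[sid].integrated)
            assert r1[sid].threshold == r2[sid].threshold

    def test_single_subject_rejected(self):
        sets, truths = self._cohort()
        with pytest.raises(TrainingError):
            run_loso(sets[:1], {"A": truths["A"]}, seed=0)
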