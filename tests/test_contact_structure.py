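"""Ensemble histograms, the prior-to-TS selector and reactive time courses."""

import numpy as np
import pytest

from conftest import make_trajectory
from hairpintse import contact_structure as cs
from hairpintse.errors import ConfigurationError, EmptyEnsembleError
from hairpintse.path_kinetics import PathSegment, segment_paths
from hairpintse.state_assignment import StateLabelSeries
from test_state_assignment import label_series


class TestHistogram:
    def test_constant_values_occupy_one_bin(self):
        h = cs.histogram_values(np.full(50, 0.42), 0.02, "TSE", "end")
        assert np.count_nonzero(h.densities) == 1
        idx = int(np.argmax(h.densities))
        assert h.bin_edges[idx] <= 0.42 <= h.bin_edges[idx + 1]

    def test_two_values_split_density(self):
        h = cs.histogram_values(np.array([0.3, 0.9]), 0.02, "e", "turn")
        occupied = h.densities[h.densities > 0]
        np.testing.assert_allclose(occupied, [0.5, 0.5])

    def test_densities_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            h = cs.histogram_values(rng.uniform(0.2, 1.5, 200), 0.02, "x", "y")
            assert h.densities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_selector_rejected(self, coordinate_data):
        traj = coordinate_data[0][0]
        with pytest.raises(EmptyEnsembleError):
            cs.ensemble_histogram(traj, [], (1, 15))


class TestPriorToTs:
    def _segment(self, start_index, traj_id="t1", dt=10.0):
        return PathSegment(traj_id, "U", "F", start_index * dt, start_index * dt,
                           dt, 1, start_index, start_index)

    def test_window_arithmetic(self):
        labels = label_series(["U"] * 600)
        labels.labels[500] = "TS"
        sel = cs.prior_to_ts_ensemble(labels, [self._segment(500)], window=1000.0)
        assert sel == list(range(400, 500))

    def test_window_clipped_at_trajectory_start(self):
        labels = label_series(["U"] * 100)
        labels.labels[30] = "TS"
        sel = cs.prior_to_ts_ensemble(labels, [self._segment(30)], window=1000.0)
        assert sel == list(range(0, 30))

    def test_overlapping_windows_union_without_duplicates(self):
        labels = label_series(["U"] * 300)
        labels.labels[100] = "TS"
        labels.labels[150] = "TS"
        segs = [self._segment(100), self._segment(150)]
        sel = cs.prior_to_ts_ensemble(labels, segs, window=1000.0)
        expected = sorted((set(range(0, 100)) | set(range(0, 150))) - {100})
        assert sel == expected

    def test_ts_and_f_frames_excluded(self):
        labels = label_series(["F"] * 50 + ["U"] * 50)
        labels.labels[90] = "TS"
        sel = cs.prior_to_ts_ensemble(labels, [self._segment(90)], window=1000.0)
        assert sel == list(range(50, 90))

    def test_disjoint_from_tse_by_construction(self):
        labels = label_series(["U", "U", "TS", "TS", "F"] * 40)
        segs = segment_paths(labels, 10.0)
        sel = cs.prior_to_ts_ensemble(labels, segs, window=200.0)
        ts_idx = {k for k, l in enumerate(labels.labels) if l == "TS"}
        assert set(sel).isdisjoint(ts_idx)

    def test_no_forward_segments_rejected(self):
        labels = label_series(["U"] * 10)
        with pytest.raises(EmptyEnsembleError):
            cs.prior_to_ts_ensemble(labels, [], window=1000.0)


class TestSubpopulations:
    def test_absent_class_is_marked_absent(self, coordinate_data):
        trajs, _ = coordinate_data
        traj = trajs[0]
        seg = PathSegment(traj.traj_id, "U", "F", 20.0, 30.0, 20.0, 2, 2, 3)
        result = cs.subpopulation_histograms([seg], traj)
        assert result["histograms"]["UTSF"] is not None
        assert result["histograms"]["FTSU"] is None
        assert result["nucleus_fraction_ftsf"] is None

    def test_single_segment_pools_exactly_its_frames(self, coordinate_data):
        trajs, _ = coordinate_data
        traj = trajs[0]
        seg = PathSegment(traj.traj_id, "U", "F", 50.0, 80.0, 40.0, 4, 5, 8)
        result = cs.subpopulation_histograms([seg], traj)
        hist = result["histograms"]["UTSF"]["end"]
        assert hist.n_frames == 4
        assert hist.densities.sum() == pytest.approx(1.0)


def test_nucleus_fraction_recovered_from_measured_segments():
    """With 65% of F-TS-F excursions emitted in the folding-nucleus geometry,
    the measured fraction of F-TS-F TS frames with the middle contact formed
    recovers the configured value within excursion-level binomial noise."""
    from hairpintse import synthetic as syn
    from hairpintse.landscape import build_landscape
    from hairpintse.order_parameters import compute_series
    from hairpintse.state_assignment import assign_states, find_basins

    cfg = syn.GeneratorConfig(
        seed=8, duration_us=0.15, n_traj=2,
        kinetics=syn.KineticsConfig(tau_u=200.0, tau_ts=10.2, tau_f=200.0),
    )
    truth = syn.simulate_states(cfg)
    trajs, ref = syn.emit_coordinates(truth, cfg)
    series = [compute_series(t, ref) for t in trajs]
    grid = build_landscape(series)
    defn = find_basins(grid)
    fractions = []
    weights = []
    n_ftsf = 0
    for traj, s in zip(trajs, series):
        segs = segment_paths(assign_states(grid, defn, s), cfg.frame_interval)
        result = cs.subpopulation_histograms(segs, traj)
        if result["nucleus_fraction_ftsf"] is not None:
            fractions.append(result["nucleus_fraction_ftsf"])
            weights.append(result["n_ftsf_ts_frames"])
        n_ftsf += sum(1 for x in segs if x.path_class == "FTSF")
    measured = float(np.average(fractions, weights=weights))
    sigma = np.sqrt(0.65 * 0.35 / n_ftsf)
    assert abs(measured - 0.65) <= 3 * sigma


class TestTimecourse:
    def _traj_and_segments(self, coordinate_data, small_truth):
        trajs, _ = coordinate_data
        for traj, tt in zip(trajs, small_truth.trajectories):
            labels = StateLabelSeries(traj.traj_id, traj.times, tt.labels())
            segs = segment_paths(labels, traj.frame_interval)
            if any(s.path_class == "UTSF" for s in segs):
                return traj, segs
        pytest.skip("no forward reactive path in fixture data")

    def test_window_zero_spans_exactly_the_ts_frames(self, coordinate_data, small_truth):
        traj, segs = self._traj_and_segments(coordinate_data, small_truth)
        bundles = cs.reactive_timecourse(segs, traj, window=0.0)
        for b in bundles:
            assert len(b.times) == b.segment.n_frames
            assert b.times[0] == b.segment.start_time
            assert b.times[-1] == b.segment.end_time

    def test_empty_observable_dict_gives_empty_bundles(self, coordinate_data, small_truth):
        traj, segs = self._traj_and_segments(coordinate_data, small_truth)
        bundles = cs.reactive_timecourse(segs, traj, observables={}, window=100.0)
        assert all(b.series == {} for b in bundles)

    def test_no_reactive_segment_rejected(self, coordinate_data):
        traj = coordinate_data[0][0]
        with pytest.raises(EmptyEnsembleError):
            cs.reactive_timecourse([], traj)

    def test_frame_annotation_brackets_the_ts_span(self, coordinate_data, small_truth):
        traj, segs = self._traj_and_segments(coordinate_data, small_truth)
        bundle = cs.reactive_timecourse(segs, traj, window=300.0)[0]
        df = bundle.to_frame()
        in_ts = df[df["in_ts"]]
        assert in_ts["time_ps"].iloc[0] == bundle.segment.start_time
        assert in_ts["time_ps"].iloc[-1] == bundle.segment.end_time
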