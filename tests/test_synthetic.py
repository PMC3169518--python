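"""Generator contracts: kinetics oracle, template geometry, mechanism encoding."""

import numpy as np
import pytest

from hairpintse import synthetic as syn
from hairpintse.errors import ConstructionError, ResolutionError
from hairpintse.order_parameters import (
    compute_distance,
    compute_distance_series,
    compute_Q,
    compute_R,
)
from hairpintse.state_assignment import StateLabelSeries
from hairpintse.path_kinetics import segment_paths


class TestSimulateStates:
    def test_same_seed_is_reproducible(self):
        cfg = syn.GeneratorConfig(seed=9, duration_us=0.01)
        a = syn.simulate_states(cfg)
        b = syn.simulate_states(cfg)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.states, tb.states)
            assert ta.excursions == tb.excursions

    def test_ts_residence_is_geometric_with_the_configured_constant(self):
        """Empirical mean residence matches the geometric expectation
        dt / (1 - exp(-dt/tau)) within 5% at >= 1e4 events."""
        cfg = syn.GeneratorConfig(
            seed=1, duration_us=3.0, n_traj=2,
            kinetics=syn.KineticsConfig(tau_u=100.0, tau_ts=10.0, tau_f=100.0),
        )
        truth = syn.simulate_states(cfg)
        res = np.array([
            (e.end - e.start + 1) * cfg.frame_interval
            for t in truth.trajectories for e in t.excursions
        ])
        assert len(res) > 1e4
        p = 1.0 - np.exp(-cfg.frame_interval / 10.0)
        expected_mean = cfg.frame_interval / p
        assert res.mean() == pytest.approx(expected_mean, rel=0.05)

    def test_full_commitment_has_no_unfolding_exits(self):
        cfg = syn.GeneratorConfig(
            seed=2, duration_us=0.05,
            kinetics=syn.KineticsConfig(tau_u=200.0, tau_ts=10.0, tau_f=200.0, p_fold=1.0),
        )
        truth = syn.simulate_states(cfg)
        classes = {e.path_class for t in truth.trajectories for e in t.excursions}
        assert "UTSU" not in classes and "FTSU" not in classes

    def test_unresolvable_basin_kinetics_rejected(self):
        with pytest.raises(ResolutionError):
            syn.simulate_states(
                syn.GeneratorConfig(kinetics=syn.KineticsConfig(tau_u=5.0), duration_us=0.01)
            )

    def test_occupancies_match_analytic_stationary_fractions(self, small_truth):
        counts = small_truth.state_counts()
        total = sum(counts.values())
        for state, fraction in small_truth.stationary.items():
            observed = counts[state] / total
            sigma = np.sqrt(fraction * (1 - fraction) / total)
            # frames are correlated within residences: allow the residence-
            # inflated binomial band
            inflation = np.sqrt(2 * 200.0 / 10.0) if state != "TS" else 2.0
            assert abs(observed - fraction) <= 5 * sigma * inflation


class TestTemplates:
    def test_native_template_is_the_reference_by_construction(self, gen_config,
                                                              native_frame, reference):
        assert compute_R(native_frame, reference) == 5.0
        assert compute_Q(native_frame, reference) == 1.0

    def test_ts_template_hits_configured_distances(self, gen_config):
        frame = syn.template_frame("ts", gen_config)
        geom = gen_config.geometry
        assert compute_distance(frame, (1, 15)) == pytest.approx(geom.ts_end, abs=0.01)
        assert compute_distance(frame, (6, 9)) == pytest.approx(geom.ts_turn, abs=0.01)
        assert compute_distance(frame, (4, 12)) == pytest.approx(geom.ts_middle, abs=0.01)

    def test_ts_template_key_lock(self, gen_config):
        frame = syn.template_frame("ts", gen_config)
        geom = gen_config.geometry
        assert compute_distance(frame, (11, 7), "sidechain_min") == pytest.approx(
            geom.w11_p7_ts, abs=0.01
        )
        assert compute_distance(frame, (11, 9), "sidechain_min") == pytest.approx(
            geom.w11_g9_ts, abs=0.01
        )

    def test_nucleus_template_shifts_w11_to_p7(self, gen_config):
        frame = syn.template_frame("nucleus", gen_config)
        geom = gen_config.geometry
        d_p7 = compute_distance(frame, (11, 7), "sidechain_min")
        d_g9 = compute_distance(frame, (11, 9), "sidechain_min")
        assert d_p7 == pytest.approx(geom.w11_p7_nucleus, abs=0.01)
        assert d_p7 < d_g9
        assert compute_distance(frame, (4, 12)) <= 0.6  # middle contacts formed

    def test_unfolded_band_r_in_expected_interval(self, gen_config, reference):
        for name in ("u", "u2", "prets"):
            r = compute_R(syn.template_frame(name, gen_config), reference)
            assert 1.8 <= r <= 2.4

    def test_infeasible_targets_raise_with_the_violated_pair(self):
        geom = syn.GeometryConfig(ts_turn=1.30)  # beyond the 3-bond contour
        with pytest.raises(ConstructionError):
            syn.build_templates(geom)


class TestEmitSeries:
    def test_seed_determinism(self, gen_config, small_truth):
        a = syn.emit_series_only(small_truth, gen_config)
        b = syn.emit_series_only(small_truth, gen_config)
        for sa_, sb in zip(a, b):
            np.testing.assert_array_equal(sa_.data.values, sb.data.values)

    def test_states_centre_on_configured_coordinates(self, gen_config, small_truth,
                                                     small_series):
        for code in (syn.STATE_U, syn.STATE_TS, syn.STATE_F):
            mu_q, mu_r = gen_config.series.centers[code]
            for tt, s in zip(small_truth.trajectories, small_series):
                mask = tt.states == code
                if mask.sum() < 100:
                    continue
                assert s.data["Q"][mask].mean() == pytest.approx(mu_q, abs=0.02)
                assert s.data["R"][mask].mean() == pytest.approx(mu_r, abs=0.05)

    def test_deviations_are_bounded(self, gen_config, small_truth, small_series):
        sc = gen_config.series
        for tt, s in zip(small_truth.trajectories, small_series):
            for code in (syn.STATE_U, syn.STATE_TS, syn.STATE_F):
                mask = tt.states == code
                dq = np.abs(s.data["Q"][mask] - sc.centers[code][0])
                assert (dq <= sc.max_z * sc.sigma_q[code] + 1e-9).all()


class TestEmitCoordinates:
    def test_mechanism_turn_before_ends(self, gen_config, small_truth, coordinate_data):
        """Along forward reactive paths, within 1 ns before TS entry the turn
        is formed while the ends are still apart."""
        trajs, _ = coordinate_data
        window = int(gen_config.geometry.approach_frames)
        turn_ok = end_ok = total = 0
        for traj, tt in zip(trajs, small_truth.trajectories):
            turn = compute_distance_series(traj, (6, 9), "calpha").values
            end = compute_distance_series(traj, (1, 15), "calpha").values
            for exc in tt.excursions:
                if exc.path_class != "UTSF" or exc.start < window:
                    continue
                pre = slice(exc.start - window, exc.start)
                if not np.all(tt.states[pre] == syn.STATE_U):
                    continue
                turn_ok += np.sum(turn[pre] < 0.8)
                end_ok += np.sum(end[pre] > 0.8)
                total += window
        assert total > 0
        assert turn_ok / total >= 0.8
        assert end_ok / total >= 0.8

    def test_hidden_excursions_recovered_from_hidden_labels(self, small_truth,
                                                            coordinate_data):
        """Geometry emission preserves the chain's excursion structure."""
        trajs, _ = coordinate_data
        for traj, tt in zip(trajs, small_truth.trajectories):
            labels = StateLabelSeries(traj.traj_id, traj.times, tt.labels())
            segs = segment_paths(labels, traj.frame_interval)
            assert len(segs) == len(tt.excursions)

    def test_nucleus_flag_rate_matches_configuration(self):
        cfg = syn.GeneratorConfig(
            seed=6, duration_us=0.4, n_traj=2,
            kinetics=syn.KineticsConfig(tau_u=200.0, tau_ts=10.2, tau_f=200.0),
        )
        truth = syn.simulate_states(cfg)
        ftsf = [e for t in truth.trajectories for e in t.excursions
                if e.path_class == "FTSF"]
        frac = np.mean([e.nucleus for e in ftsf])
        sigma = np.sqrt(0.65 * 0.35 / len(ftsf))
        assert abs(frac - 0.65) <= 3 * sigma
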