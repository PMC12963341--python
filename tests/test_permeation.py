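"""Crossing detection, the counting equations, aggregation and RMSD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poreflux import permeation
from poreflux.permeation import (
    CrossingEvent,
    PoreGeometry,
    aggregate_replicates,
    compute_conductance,
    compute_current,
    count_directional,
    detect_crossings,
    kabsch_rmsd,
    rmsd_series,
    unwrap_z,
    wrap_z,
)

from conftest import traj_from_z


def fsm_oracle(path, z_lo, z_hi, box_z):
    """Frame-by-frame hysteresis automaton over every periodic plane image."""
    events = []
    lo_img = int(np.floor((min(path) - z_lo) / box_z)) - 1
    hi_img = int(np.ceil((max(path) - z_lo) / box_z)) + 1
    for k in range(lo_img, hi_img + 1):
        lo = z_lo + k * box_z
        hi = z_hi + k * box_z
        state = None
        for z in path:
            region = "B" if z < lo else ("A" if z >= hi else "M")
            if region == "M":
                continue
            if state is None:
                state = region
            elif region != state:
                events.append(+1 if region == "A" else -1)
                state = region
    return sorted(events)


class TestUnwrap:
    def test_no_wrap_passthrough(self):
        out = unwrap_z([1.0, 1.2, 1.4], 12.0)
        assert out == pytest.approx([1.0, 1.2, 1.4])

    def test_single_wrap_minimal_image(self):
        assert unwrap_z([11.8, 0.2], 12.0) == pytest.approx([11.8, 12.2])

    def test_downward_wrap(self):
        assert unwrap_z([0.2, 11.8], 12.0) == pytest.approx([0.2, -0.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unwrap_z([], 12.0)

    def test_half_box_jump_tie_rule_is_no_wrap(self):
        assert unwrap_z([0.0, 6.0], 12.0) == pytest.approx([0.0, 6.0])

    @given(seed=st.integers(0, 500), box=st.floats(5.0, 30.0))
    def test_round_trip_and_step_bound_on_random_walks(self, seed, box):
        rng = np.random.default_rng(seed)
        true = np.cumsum(rng.normal(0, box / 6, size=60))
        wrapped = true % box
        unwrapped = unwrap_z(wrapped, box)
        assert np.allclose(wrap_z(unwrapped, box), wrapped, atol=1e-9)
        assert np.all(np.abs(np.diff(unwrapped)) <= box / 2 + 1e-9)
        k = (unwrapped - wrapped) / box
        assert np.allclose(k, np.round(k), atol=1e-9)


class TestDetectCrossings:
    GEOM = PoreGeometry(4.0, 8.0)

    def test_monotone_traversal_is_one_up_event(self, z_traj_builder):
        traj = z_traj_builder(np.linspace(0, 12, 25))
        evs = detect_crossings(traj, self.GEOM)
        assert [e.direction for e in evs] == [1]

    def test_dip_into_slab_does_not_double_count(self, z_traj_builder):
        traj = z_traj_builder([0.0, 7.0, 3.0, 12.0])
        evs = detect_crossings(traj, self.GEOM)
        assert [e.direction for e in evs] == [1]
        # matches the independent automaton
        assert fsm_oracle([0.0, 7.0, 3.0, 12.0], 4.0, 8.0, 100.0) == [1]

    def test_oscillation_inside_slab_never_fires(self, z_traj_builder):
        traj = z_traj_builder([5.0, 7.0] * 20)
        assert detect_crossings(traj, self.GEOM) == []

    def test_recrossing_counts_as_new_event(self, z_traj_builder):
        traj = z_traj_builder([0.0, 12.0, 0.0, 12.0])
        evs = detect_crossings(traj, self.GEOM)
        assert [e.direction for e in evs] == [1, -1, 1]
        assert all(e.flagged_sparse for e in evs)  # single-frame jumps flagged

    def test_periodic_recycling_is_not_a_crossing(self, z_traj_builder):
        # ion drifts up through the periodic boundary within the reservoir:
        # wrapped z jumps 11.8 -> 0.2 without passing through the pore
        traj = z_traj_builder(np.array([9.0, 10.5, 11.8, 12.2, 13.5]) % 12.0,
                              box_z=12.0)
        assert detect_crossings(traj, self.GEOM) == []

    def test_wrapped_full_translocation_counts_once(self, z_traj_builder):
        true = np.linspace(6.0, 22.0, 60)  # passes slab image at 16..20
        traj = z_traj_builder(true % 12.0, box_z=12.0)
        evs = detect_crossings(traj, self.GEOM)
        assert [e.direction for e in evs] == [1]

    def test_planes_outside_range_warn_and_return_empty(self, z_traj_builder):
        traj = z_traj_builder(np.linspace(0, 10, 10), box_z=12.0)
        with pytest.warns(UserWarning):
            assert detect_crossings(traj, PoreGeometry(-5.0, 20.0)) == []

    def test_entry_exit_times_ordered_and_disjoint(self, z_traj_builder):
        rng = np.random.default_rng(3)
        path = np.cumsum(rng.normal(0.4, 1.2, size=300))
        traj = z_traj_builder(path)
        evs = detect_crossings(traj, self.GEOM)
        for e in evs:
            assert e.entry_time_ns < e.exit_time_ns

    @given(seed=st.integers(0, 300))
    def test_matches_brute_force_automaton_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(0.0, 2.0, size=120)) + 6.0
        traj = traj_from_z(path, box_z=1000.0)
        got = sorted(e.direction for e in detect_crossings(traj, self.GEOM))
        assert got == fsm_oracle(path, 4.0, 8.0, 1000.0)

    @given(seed=st.integers(0, 200), shift=st.floats(0.0, 200.0))
    def test_invariant_under_rigid_translation_with_geometry(self, seed, shift):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(0.2, 1.5, size=100)) + 300.0
        a = detect_crossings(
            traj_from_z(path, 1000.0), PoreGeometry(298.0, 302.0)
        )
        b = detect_crossings(
            traj_from_z(path + shift, 1000.0),
            PoreGeometry(298.0 + shift, 302.0 + shift),
        )
        assert [e.direction for e in a] == [e.direction for e in b]

    @given(seed=st.integers(0, 200))
    def test_time_reversal_negates_directions(self, seed):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(0.1, 1.5, size=100)) + 6.0
        fwd = sorted(e.direction for e in
                     detect_crossings(traj_from_z(path, 1000.0), self.GEOM))
        rev = sorted(-e.direction for e in
                     detect_crossings(traj_from_z(path[::-1], 1000.0), self.GEOM))
        assert fwd == rev


class TestCounting:
    def _ev(self, species, direction):
        return CrossingEvent(0, species, direction, 0.0, 1.0)

    def test_empty_is_zero(self):
        c = count_directional([])
        assert tuple(c) == (0, 0)

    def test_manual_tally(self):
        evs = (
            [self._ev("K+", 1)] * 3
            + [self._ev("K+", -1)]
            + [self._ev("Cl-", -1)] * 2
        )
        c = count_directional(evs)
        assert (c.n_k, c.n_cl) == (3, 2)
        assert (c.n_k_counter, c.n_cl_counter) == (1, 0)

    def test_wrong_direction_chloride_excluded(self):
        c = count_directional([self._ev("Cl-", 1)] * 5)
        assert tuple(c) == (0, 0)
        assert c.n_cl_counter == 5

    def test_current_zero_counts(self):
        assert compute_current(0, 0, 7.0) == 0.0

    def test_current_single_charge_per_ns(self):
        # 1.602e-19 C / 1e-9 s = 1.602e-10 A = 160.2 pA
        assert compute_current(1, 0, 1.0) == pytest.approx(160.2)

    def test_current_matches_reported_triplicate_scale(self):
        # 130 productive crossings over 500 ns: within 1 pA of 41.54 pA
        assert compute_current(65, 65, 500.0) == pytest.approx(41.652)
        assert abs(compute_current(65, 65, 500.0) - 41.54) < 1.0

    def test_current_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            compute_current(1, 1, 0.0)

    def test_conductance_worked_examples(self):
        g_wt = compute_conductance(41.54, 150.0)
        assert g_wt == pytest.approx(0.27693, abs=1e-4)
        assert round(g_wt, 2) == 0.28
        g_mut = compute_conductance(60.02, 150.0)
        assert g_mut == pytest.approx(0.40013, abs=1e-4)
        assert round(g_mut, 2) == 0.40
        assert compute_conductance(0.0, 150.0) == 0.0

    def test_conductance_rejects_zero_voltage(self):
        with pytest.raises(ValueError):
            compute_conductance(10.0, 0.0)

    @given(
        n_k=st.integers(0, 10_000),
        n_cl=st.integers(0, 10_000),
        dt=st.floats(1e-3, 1e6),
        v=st.floats(1.0, 500.0),
    )
    def test_identities_to_machine_precision(self, n_k, n_cl, dt, v):
        i = compute_current(n_k, n_cl, dt)
        assert i == pytest.approx((n_k + n_cl) * 1.602e-19 / (dt * 1e-9) * 1e12,
                                  rel=1e-12)
        assert compute_conductance(i, v) == pytest.approx(i / v, rel=1e-12)


class TestAggregate:
    def _est(self, i, v=150.0):
        from poreflux.permeation import ConductanceEstimate, DirectionalCounts

        return ConductanceEstimate(
            counts=DirectionalCounts(0, 0, 0, 0),
            dt_ns=500.0,
            voltage_mV=v,
            current_pA=i,
            conductance_nS=i / v,
        )

    def test_hand_mean_and_sd(self):
        agg = aggregate_replicates([self._est(40.0), self._est(42.0), self._est(44.0)])
        assert agg.mean_current_pA == pytest.approx(42.0)
        assert agg.sd_current_pA == pytest.approx(2.0)
        assert agg.n == 3

    def test_single_replicate_flagged_sd_zero(self):
        agg = aggregate_replicates([self._est(40.0)])
        assert agg.single_replicate and agg.sd_current_pA == 0.0

    def test_equal_values_zero_sd(self):
        agg = aggregate_replicates([self._est(40.0)] * 3)
        assert agg.sd_conductance_nS == 0.0

    def test_mixed_voltages_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([self._est(40.0, 150.0), self._est(40.0, 100.0)])


class TestRMSD:
    def test_identical_sets_zero(self):
        c = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed_by_superposition(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = c @ rot.T + np.array([1.0, -2.0, 3.0])
        assert kabsch_rmsd(c, moved, superpose=True) <= 1e-10
        assert kabsch_rmsd(c, moved, superpose=False) > 0.5

    def test_raw_rmsd_equals_displacement(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        frame = ref + np.array([0.0, 0.3, 0.0])
        assert kabsch_rmsd(ref, frame, superpose=False) == pytest.approx(0.3)

    def test_too_few_atoms_for_superposition(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.ones((2, 3)), superpose=True)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_series_static_structure_all_zero(self):
        c = np.random.default_rng(2).normal(size=(8, 3))
        series = rmsd_series(np.repeat(c[None], 5, axis=0))
        assert np.allclose(series, 0.0, atol=1e-12)

    def test_series_pure_drift_superposed_away(self):
        c = np.random.default_rng(3).normal(size=(8, 3))
        frames = np.stack([c + k * np.array([0.5, 0.0, 0.0]) for k in range(6)])
        assert np.allclose(rmsd_series(frames), 0.0, atol=1e-10)

    def test_series_matches_per_frame_hand_calls(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(3, 6, 3))
        series = rmsd_series(frames, reference_frame=0)
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        for k in range(3):
            assert series[k] == pytest.approx(
                kabsch_rmsd(frames[0], frames[k]), abs=1e-12
            )

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            rmsd_series(np.empty((0, 4, 3)))
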