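"""Tissue-level physics: quiescence, wavefront causality and uniqueness,
conduction-velocity anisotropy, sqrt(D) wave-speed scaling, conduction
block, CFL guard, and trace I/O."""

import numpy as np
import pytest

from fibwave.ionic import make_profile
from fibwave.monodomain import (CFLError, PropagationError, SimulationTrace,
                                SolverConfig, StimulusEvent, TuningError,
                                apply_conduction_block, max_stable_dt,
                                measure_cv, simulate, tune_diffusion)
from fibwave.tissue import (SIGMA_L_NONFIB, SIGMA_T_NONFIB, TissueConfig,
                            TissueModel, generate_substrate)


def uniform_sheet(nx=40, ny=40, dx_mm=0.3, angle=0.0):
    x = np.arange(nx) * dx_mm
    y = np.arange(ny) * dx_mm
    xx, yy = np.meshgrid(x, y)
    coords = np.column_stack([xx.reshape(-1), yy.reshape(-1)])
    n = nx * ny
    return TissueModel(nx, ny, dx_mm * 1000.0, coords,
                       np.full(n, angle), np.full(n, 2.0),
                       np.zeros(n, dtype=bool), np.full(n, SIGMA_L_NONFIB),
                       np.full(n, SIGMA_T_NONFIB), np.ones(n, dtype=int),
                       [], np.zeros(n, dtype=bool))


PROFILE = make_profile("control")


class TestQuiescenceAndCausality:
    def test_no_stimulus_stays_at_rest(self):
        tissue = uniform_sheet(20, 20)
        trace = simulate(tissue, PROFILE, [], 500.0, SolverConfig())
        assert np.max(np.abs(trace.V - trace.V[0, 0])) < 1.0
        assert all(a.size == 0 for a in trace.activation_times())

    def test_no_activation_before_stimulus(self):
        tissue = uniform_sheet(20, 20)
        stim = StimulusEvent(100.0, np.array([0, 1, 2, 20, 21, 22]), 60.0, 2.0)
        trace = simulate(tissue, PROFILE, [stim], 400.0)
        for a in trace.activation_times():
            assert a.size == 0 or a[0] >= 100.0


class TestWavefront:
    @pytest.fixture(scope="class")
    def corner_trace(self):
        tissue = uniform_sheet(40, 40)
        corner = np.flatnonzero(
            (tissue.node_coords[:, 0] < 1.0) & (tissue.node_coords[:, 1] < 1.0))
        stim = StimulusEvent(2.0, corner, 60.0, 2.0)
        return tissue, simulate(tissue, PROFILE, [stim], 600.0)

    def test_every_node_activates_exactly_once(self, corner_trace):
        _, trace = corner_trace
        counts = np.array([a.size for a in trace.activation_times()])
        assert np.all(counts == 1)

    def test_activation_time_grows_with_distance(self, corner_trace):
        tissue, trace = corner_trace
        first = np.array([a[0] for a in trace.activation_times()])
        d = np.linalg.norm(tissue.node_coords, axis=1)
        order = np.argsort(d)
        # binned monotonicity (the front is convex but anisotropic)
        nb = 8
        bins = np.array_split(order, nb)
        means = [first[b].mean() for b in bins]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestConductionVelocity:
    def test_cv_arithmetic(self):
        # distance 6 mm, delay 10 ms -> 0.6 m/s
        trace = SimulationTrace(1.0, 100.0,
                                np.zeros((100, 2), dtype=np.float32), [],
                                np.array([[0.0, 0.0], [6.0, 0.0]]))
        trace._activations = [np.array([5.0]), np.array([15.0])]
        assert measure_cv(trace, 0, 1) == pytest.approx(0.6)

    def test_unactivated_target_raises(self):
        trace = SimulationTrace(1.0, 100.0,
                                np.zeros((100, 2), dtype=np.float32), [],
                                np.array([[0.0, 0.0], [6.0, 0.0]]))
        trace._activations = [np.array([5.0]), np.empty(0)]
        with pytest.raises(PropagationError):
            measure_cv(trace, 0, 1)

    @pytest.fixture(scope="class")
    def center_paced(self):
        tissue = uniform_sheet(61, 61, dx_mm=0.25, angle=0.0)
        center = 30 * 61 + 30
        stim = StimulusEvent(2.0, np.array([center + o for o in
                                            (-62, -61, -60, -1, 0, 1, 60, 61, 62)]),
                             60.0, 2.0)
        trace = simulate(tissue, PROFILE, [stim], 120.0)
        return tissue, trace, center

    def test_anisotropy_ratio_above_threshold(self, center_paced):
        tissue, trace, center = center_paced
        along = center + 22          # +x, along fibers
        across = center + 22 * 61    # +y
        cv_l = measure_cv(trace, center, along)
        cv_t = measure_cv(trace, center, across)
        assert cv_l / cv_t > 1.5

    def test_wavespeed_scales_as_sqrt_diffusion(self):
        tissue = uniform_sheet(81, 7, dx_mm=0.2)
        left = np.flatnonzero(tissue.node_coords[:, 0] < 0.5)
        a = 3 * 81 + 20
        b = 3 * 81 + 60
        cvs = []
        for factor in (1.0, 4.0):
            sol = SolverConfig(dt=0.02, diffusion_scale=1.2 * factor)
            trace = simulate(tissue, PROFILE,
                             [StimulusEvent(2.0, left, 60.0, 2.0)], 80.0, sol)
            cvs.append(measure_cv(trace, a, b))
        assert cvs[1] / cvs[0] == pytest.approx(2.0, rel=0.10)


class TestTuneDiffusion:
    def test_fixed_point_returns_unity(self):
        tissue = uniform_sheet(10, 10, dx_mm=0.3)
        sol = SolverConfig()
        from fibwave.monodomain import _probe_cv
        baseline = _probe_cv(0.3, PROFILE, sol, 1.0)
        factor, achieved = tune_diffusion(tissue, baseline, tolerance=0.05)
        assert 0.7 < factor < 1.4
        assert achieved == pytest.approx(baseline, rel=0.05)

    def test_zero_target_fails(self):
        tissue = uniform_sheet(10, 10)
        with pytest.raises(TuningError):
            tune_diffusion(tissue, 0.0)


class TestConductionBlock:
    def test_blocked_disc_never_activates(self):
        tissue = uniform_sheet(40, 40)
        coords = tissue.node_coords
        center = np.array([6.0, 6.0])
        disc = np.flatnonzero(np.linalg.norm(coords - center, axis=1) < 2.0)
        blocked = apply_conduction_block(tissue, disc)
        corner = np.flatnonzero((coords[:, 0] < 1.0) & (coords[:, 1] < 1.0))
        trace = simulate(blocked, PROFILE,
                         [StimulusEvent(2.0, corner, 60.0, 2.0)], 600.0)
        acts = trace.activation_times()
        assert all(acts[k].size == 0 for k in disc)
        outside = np.setdiff1d(np.flatnonzero(blocked.active), disc)
        assert all(acts[k].size == 1 for k in outside)

    def test_full_width_line_confines_activation(self):
        tissue = uniform_sheet(40, 40)
        line = np.flatnonzero(np.abs(tissue.node_coords[:, 0] - 6.0) < 0.3)
        blocked = apply_conduction_block(tissue, line)
        left = np.flatnonzero(tissue.node_coords[:, 0] < 0.5)
        trace = simulate(blocked, PROFILE,
                         [StimulusEvent(2.0, left, 60.0, 2.0)], 500.0)
        acts = trace.activation_times()
        right_side = np.flatnonzero(blocked.node_coords[:, 0] > 6.5)
        assert all(acts[k].size == 0 for k in right_side)

    def test_idempotent_and_cumulative(self):
        tissue = uniform_sheet(10, 10)
        once = apply_conduction_block(tissue, [5, 6])
        twice = apply_conduction_block(once, [5, 6])
        np.testing.assert_array_equal(once.ablated, twice.ablated)
        more = apply_conduction_block(twice, [7])
        assert more.ablated[[5, 6, 7]].all()

    def test_empty_set_warns_no_op(self):
        tissue = uniform_sheet(10, 10)
        with pytest.warns(UserWarning):
            out = apply_conduction_block(tissue, [])
        assert not out.ablated.any()


class TestGuards:
    def test_cfl_violation_reports_admissible_dt(self):
        tissue = uniform_sheet(10, 10, dx_mm=0.1)
        sol = SolverConfig(dt=0.05, diffusion_scale=30.0)
        with pytest.raises(CFLError, match="admissible"):
            simulate(tissue, PROFILE, [], 10.0, sol)
        assert max_stable_dt(tissue, sol) < 0.05

    def test_dt_refinement_shifts_activation_under_two_percent(self):
        tissue = uniform_sheet(30, 8, dx_mm=0.3)
        left = np.flatnonzero(tissue.node_coords[:, 0] < 0.4)
        probe = 4 * 30 + 25
        times = []
        for dt in (0.025, 0.0125):
            trace = simulate(tissue, PROFILE,
                             [StimulusEvent(2.0, left, 60.0, 2.0)], 80.0,
                             SolverConfig(dt=dt, dt_record=0.25))
            times.append(trace.activation_times()[probe][0])
        assert abs(times[0] - times[1]) / times[1] < 0.02

    def test_trace_roundtrip(self, tmp_path):
        tissue = uniform_sheet(10, 10)
        stim = StimulusEvent(2.0, np.array([0, 1]), 60.0, 2.0)
        trace = simulate(tissue, PROFILE, [stim], 50.0)
        path = tmp_path / "trace.h5"
        trace.save(path)
        back = SimulationTrace.load(path)
        np.testing.assert_array_equal(back.V, trace.V)
        assert back.dt_record == trace.dt_record
        assert len(back.stimulus_log) == 1
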