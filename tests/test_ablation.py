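"""Virtual ablation: CPVI ring geometry and closure, DF-target sets,
rhythm classification on constructed rhythms, and experiment bookkeeping."""

import numpy as np
import pytest
from scipy import ndimage

from fibwave.ablation import (AblationError, RhythmOutcome, classify_rhythm,
                              cpvi_set, df_ablation_set,
                              run_ablation_experiment)
from fibwave.dfmap import DFMap
from fibwave.ionic import make_profile
from fibwave.monodomain import SimulationTrace, apply_conduction_block
from fibwave.protocols import RampProtocol
from fibwave.tissue import TissueConfig, generate_substrate


@pytest.fixture(scope="module")
def pv_tissue():
    cfg = TissueConfig(nx=60, ny=60, spacing_um=500, n_samples=200,
                       n_patches=0, pv_radius_mm=2.0)
    return generate_substrate(cfg, seed=3)[0]


class TestCPVI:
    def test_rings_isolate_every_opening(self, pv_tissue):
        ring = cpvi_set(pv_tissue)
        assert ring.size > 0
        blocked = apply_conduction_block(pv_tissue, ring)
        grid = (blocked.active).reshape(60, 60)
        labels, n = ndimage.label(grid, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        # the sheet splits into an exterior plus one pocket per opening
        assert n >= 1 + len(pv_tissue.pv_openings)
        ext = labels[0, 0]
        coords = pv_tissue.node_coords
        for cx, cy, r in pv_tissue.pv_openings:
            d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
            rim = np.flatnonzero(blocked.active & (d > r) & (d < r + 0.9))
            assert rim.size > 0
            assert np.all(labels.reshape(-1)[rim] != ext)

    def test_margin_zero_hugs_rim(self, pv_tissue):
        tight = cpvi_set(pv_tissue, margin_mm=0.0)
        wide = cpvi_set(pv_tissue, margin_mm=1.5)
        coords = pv_tissue.node_coords
        cx, cy, r = pv_tissue.pv_openings[0]

        def min_gap(nodes):
            d = np.hypot(coords[nodes, 0] - cx, coords[nodes, 1] - cy)
            return (d - r).min()

        assert min_gap(tight) < min_gap(wide)

    def test_no_openings_is_error(self):
        cfg = TissueConfig(nx=20, ny=20, n_samples=50, n_patches=0,
                           pv_radius_mm=0.2, pv_centers_frac=())
        tissue = generate_substrate(cfg, seed=0)[0]
        with pytest.raises(AblationError):
            cpvi_set(tissue)

    def test_ring_out_of_bounds_is_error(self):
        cfg = TissueConfig(nx=24, ny=24, spacing_um=500, n_samples=50,
                           n_patches=0, pv_radius_mm=2.0,
                           pv_centers_frac=((0.1, 0.1),))
        tissue = generate_substrate(cfg, seed=0)[0]
        with pytest.raises(AblationError, match="bounds"):
            cpvi_set(tissue, margin_mm=2.0)


class TestDFTarget:
    def _map(self, values):
        df = np.asarray(values, dtype=float)[:, None]
        return DFMap(((0.0, 6.0),), df, 1 / 6, np.nanmean(df, axis=0), {})

    def _tissue(self, n):
        cfg = TissueConfig(nx=n, ny=1, spacing_um=500, n_samples=2,
                           n_patches=0, pv_radius_mm=0.01, pv_centers_frac=())
        # 1-row strip: build directly
        from fibwave.tissue import TissueModel
        coords = np.column_stack([np.arange(n) * 0.5, np.zeros(n)])
        return TissueModel(n, 1, 500.0, coords, np.zeros(n), np.full(n, 2.0),
                           np.zeros(n, bool), np.full(n, 0.1264),
                           np.full(n, 0.0252), np.ones(n, int), [],
                           np.zeros(n, bool))

    def test_confined_to_high_frequency_nodes(self):
        tissue = self._tissue(4)
        sel = df_ablation_set(self._map([8.0, 7.7, 7.5, 6.0]), 0, tissue)
        assert list(sel) == [0, 1]

    def test_excludes_already_ablated(self):
        tissue = self._tissue(4)
        tissue.ablated[0] = True
        sel = df_ablation_set(self._map([8.0, 7.9, 6.0, 5.0]), 0, tissue)
        assert list(sel) == [1]

    def test_empty_after_exclusion_is_error(self):
        tissue = self._tissue(3)
        tissue.ablated[:] = True
        with pytest.raises(AblationError):
            df_ablation_set(self._map([8.0, 6.0, 5.0]), 0, tissue)

    def test_uniform_map_warns(self):
        tissue = self._tissue(5)
        with pytest.warns(UserWarning, match="uniform"):
            sel = df_ablation_set(self._map([7.0] * 5), 0, tissue)
        assert sel.size == 5


def synthetic_trace(signals, dt=1.0):
    V = np.asarray(signals, dtype=np.float32).T
    return SimulationTrace(dt, V.shape[0] * dt, V, [],
                           np.zeros((V.shape[1], 2)))


def ap_train(cl, dur_ms, phase_ms=0.0, apd_frac=0.45, jitter=None, rng=None):
    t = np.arange(dur_ms)
    if jitter:
        cl_seq = cl + rng.normal(0, jitter * cl, int(dur_ms / cl) + 3)
        onsets = phase_ms + np.cumsum(np.r_[0.0, cl_seq])
        v = np.full(t.shape, -80.0)
        for on in onsets:
            v[(t >= on) & (t < on + apd_frac * cl)] = 10.0
        return v
    phase = ((t - phase_ms) % cl) / cl
    return np.where(phase < apd_frac, 10.0, -80.0)


class TestClassifyRhythm:
    def test_quiescent_window_terminated(self):
        trace = synthetic_trace([np.full(3000, -80.0)] * 8)
        out = classify_rhythm(trace, (500.0, 2800.0))
        assert out.label == "TERMINATED"
        assert out.defragmented

    def test_periodic_reentry_is_at(self):
        # 5 Hz circulating activity: identical CL everywhere, staggered phase
        n = 16
        sigs = [ap_train(200.0, 4000, phase_ms=12.5 * k) for k in range(n)]
        out = classify_rhythm(synthetic_trace(sigs), (200.0, 3800.0))
        assert out.label == "AT"
        assert out.mean_cycle_length == pytest.approx(200.0, abs=5.0)
        assert out.defragmented

    def test_irregular_multifrequency_is_af(self):
        rng = np.random.default_rng(8)
        sigs = []
        for k in range(16):
            cl = float(rng.uniform(120, 260))
            sigs.append(ap_train(cl, 4000, phase_ms=float(rng.uniform(0, 200)),
                                 jitter=0.18, rng=rng))
        out = classify_rhythm(synthetic_trace(sigs), (200.0, 3800.0))
        assert out.label == "AF"
        assert not out.defragmented

    def test_window_outside_trace_rejected(self):
        trace = synthetic_trace([np.full(1000, -80.0)] * 2)
        with pytest.raises(ValueError):
            classify_rhythm(trace, (500.0, 5000.0))


class TestExperiment:
    def test_uninducible_baseline_skips(self):
        # homogeneous small sheet, control profile: activity dies with pacing
        cfg = TissueConfig(nx=30, ny=30, spacing_um=500, n_samples=100,
                           n_patches=0, pv_radius_mm=1.2)
        tissue = generate_substrate(cfg, seed=1)[0]
        proto = RampProtocol(cl_start=200.0, cl_end=180.0, beats_per_cl=2)
        rep = run_ablation_experiment(tissue, make_profile("control"),
                                      proto, "cpvi_only")
        assert rep.skipped
        assert not rep.baseline_induced
        assert rep.outcome is None

    def test_unknown_arm_rejected(self):
        cfg = TissueConfig(nx=20, ny=20, n_samples=50, n_patches=0,
                           pv_radius_mm=0.5)
        tissue = generate_substrate(cfg, seed=0)[0]
        with pytest.raises(AblationError):
            run_ablation_experiment(tissue, make_profile("control"),
                                    RampProtocol(), "nonsense")

    def test_paired_arms_differ_only_in_df_set(self, pv_tissue):
        ring = cpvi_set(pv_tissue)
        base = apply_conduction_block(pv_tissue, ring)
        df_vals = np.full(pv_tissue.n_nodes, 5.0)
        df_vals[:40] = 8.0
        dfm = DFMap(((0.0, 6.0),), df_vals[:, None], 1 / 6,
                    np.array([5.2]), {})
        target = df_ablation_set(dfm, 0, base)
        plus = apply_conduction_block(base, target)
        diff = np.flatnonzero(plus.ablated != base.ablated)
        np.testing.assert_array_equal(diff, np.sort(target))
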