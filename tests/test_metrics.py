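"""Metric definitions: statistics oracles, conventions, invariances."""

import numpy as np
import pytest

from aortaflow import geometry as G
from aortaflow import metrics as M
from aortaflow.rt import RTField


class TestRTStats:
    def test_matches_brute_force_cell_quadrature(self, root_mesh_2d, rng):
        """Vectorized statistics equal an independent per-cell summation."""
        mesh = root_mesh_2d
        n = mesh.vertices.shape[0]
        rel = rng.uniform(0.0, 1.0, n)
        got = M.rt_stats(RTField(rel, 1.0), mesh)

        fd = mesh.fem()
        tot = vol_gt = acc = 0.0
        mx = 0.0
        for cell, vol in zip(fd.cells, fd.vol):     # plain-python oracle
            avg = sum(rel[i] for i in cell) / len(cell)
            tot += vol
            acc += vol * avg
            if avg > 0.2:
                vol_gt += vol
        mx = max(rel[i] for cell in fd.cells for i in cell)
        assert got["rt_mean"] == pytest.approx(acc / tot, rel=1e-12)
        assert got["rt_max"] == pytest.approx(mx, rel=1e-12)
        assert got["pct_vol_rt_gt_02"] == pytest.approx(100 * vol_gt / tot,
                                                        rel=1e-12)

    def test_uniform_field_statistics(self, cavity_mesh):
        n = cavity_mesh.vertices.shape[0]
        got = M.rt_stats(np.ones(n), cavity_mesh)
        assert got == {"rt_mean": pytest.approx(1.0),
                       "rt_max": pytest.approx(1.0),
                       "pct_vol_rt_gt_02": pytest.approx(100.0)}
        low = M.rt_stats(np.full(n, 0.15), cavity_mesh)
        assert low["pct_vol_rt_gt_02"] == 0.0

    def test_mean_bounded_by_max_and_threshold_consistency(self, channel_mesh,
                                                           rng):
        n = channel_mesh.vertices.shape[0]
        rel = rng.uniform(0.0, 0.19, n)
        got = M.rt_stats(rel, channel_mesh)
        assert got["rt_mean"] <= got["rt_max"]
        assert got["pct_vol_rt_gt_02"] == 0.0       # max below threshold


class TestConventions:
    @pytest.mark.parametrize("treatment,control,expected", [
        (0.6, 1.0, 40.0), (1.0, 1.0, 0.0), (1.2, 1.0, -20.0)])
    def test_percent_change_decrease_convention(self, treatment, control,
                                                expected):
        assert M.percent_change(treatment, control) == pytest.approx(expected)

    def test_percent_change_zero_control(self):
        with pytest.raises(M.UndefinedComparisonError):
            M.percent_change(1.0, 0.0)

    def test_group_normalize(self):
        assert M.group_normalize([2.0, 4.0]) == [0.5, 1.0]
        assert M.group_normalize([7.0]) == [1.0]
        with pytest.raises(M.UndefinedComparisonError):
            M.group_normalize([0.0, 0.0])

    def test_group_normalize_max_is_one(self, rng):
        vals = rng.uniform(0.1, 9.0, 17)
        assert max(M.group_normalize(vals)) == pytest.approx(1.0)


class _Hist:
    def __init__(self, **kw):
        self.__dict__.update(kw)


def _tpg_history(p_in, p_meas, open_mask):
    n = len(p_in)
    return _Hist(cycle=np.zeros(n, dtype=int), valve_open=np.asarray(open_mask),
                 p_in_avg=np.asarray(p_in, dtype=float),
                 p_meas_avg=np.asarray(p_meas, dtype=float),
                 vmax_down=None)


class TestTPG:
    def test_gauge_invariance(self):
        """Adding a constant to every pressure leaves the mean TPG unchanged."""
        rngl = np.random.default_rng(3)
        p_in = rngl.uniform(9e3, 14e3, 40)
        p_ds = rngl.uniform(9e3, 14e3, 40)
        mask = np.arange(40) < 15
        h1 = _tpg_history(p_in, p_ds, mask)
        h2 = _tpg_history(p_in + 777.7, p_ds + 777.7, mask)
        assert M.mean_tpg(h1) == pytest.approx(M.mean_tpg(h2), rel=1e-12)

    def test_positive_part_convention(self):
        """Downstream pressure above the inlet at all times gives zero TPG."""
        h = _tpg_history([1.0, 1.0], [5.0, 5.0], [True, True])
        assert M.mean_tpg(h) == 0.0

    def test_uniform_pressure_gives_zero(self):
        h = _tpg_history([3.0, 3.0], [3.0, 3.0], [True, True])
        assert M.mean_tpg(h) == 0.0

    def test_forward_flow_window_only(self):
        """Diastolic (closed-valve) samples do not enter the average."""
        h = _tpg_history([10.0, 99.0], [0.0, 0.0], [True, False])
        assert M.mean_tpg(h) == pytest.approx(10.0)


class TestPeakVelocity:
    def test_rotation_invariance(self):
        """Rigid rotation about the axial direction preserves the peak."""
        params = G.RootParameters(goa_diameter=17.0)
        mesh = G.build_root_mesh(params, 2.5, "3d")
        n = mesh.vertices.shape[0]
        rngl = np.random.default_rng(11)
        v = rngl.normal(size=(n, 3)) * 100.0
        th = np.radians(37.0)
        R = np.array([[np.cos(th), -np.sin(th), 0.0],
                      [np.sin(th), np.cos(th), 0.0],
                      [0.0, 0.0, 1.0]])
        rot = G.TaggedMesh(mesh.vertices @ R.T, mesh.cells, mesh.facets,
                           mesh.facet_tags, mesh.characteristic_edge_length,
                           mesh.meta, mesh.node_pairs)
        assert M.peak_velocity_field(v @ R.T, rot) == pytest.approx(
            M.peak_velocity_field(v, mesh), rel=1e-12)

    def test_uniform_downstream_field(self, root_mesh_2d):
        mesh = root_mesh_2d
        n = mesh.vertices.shape[0]
        v = np.zeros((n, 2))
        z = mesh.vertices[:, 1]
        v[(z > mesh.meta["z_valve"]), 0] = 250.0
        assert M.peak_velocity_field(v, mesh) == pytest.approx(250.0)

    def test_zero_flow_gives_zero(self, root_mesh_2d):
        n = root_mesh_2d.vertices.shape[0]
        assert M.peak_velocity_field(np.zeros((n, 2)), root_mesh_2d) == 0.0

    def test_continuity_lower_bound_through_orifice(self, baseline_run):
        """Peak jet speed is at least the peak flux over the orifice width."""
        from aortaflow.bcs import planar_flux_factor
        h = baseline_run.history
        mesh = baseline_run.mesh
        q_peak = h.q_in.max()                     # mesh (planar) flux units
        goa_width = 2.0 * mesh.meta["orifice_radius"]
        tol = 1.10                                 # one-facet discretization
        assert M.peak_velocity(h, mesh) * tol >= q_peak / goa_width


class TestReports:
    def _rep(self, label, pv, tpg, rtm):
        return M.MetricsReport(scenario=label, peak_velocity=pv, mean_tpg=tpg,
                               rt_mean=rtm, rt_max=2 * rtm,
                               pct_vol_rt_gt_02=1.0)

    def test_comparison_table_identity_case(self):
        reps = [self._rep("a", 10.0, 5.0, 0.1), self._rep("b", 10.0, 5.0, 0.1)]
        df = M.comparison_table(reps, "a")
        assert np.allclose(df["peak_velocity_normalized"], 1.0)
        assert np.allclose(df["peak_velocity_pct_change_vs_a"], 0.0)

    def test_comparison_table_three_scenarios(self):
        reps = [self._rep("a", 10.0, 5.0, 0.1), self._rep("b", 6.0, 2.0, 0.08),
                self._rep("c", 12.0, 7.0, 0.12)]
        df = M.comparison_table(reps, "a")
        for c in ("peak_velocity", "mean_tpg", "rt_mean"):
            assert df[f"{c}_normalized"].max() == pytest.approx(1.0)
        assert df.loc["b", "peak_velocity_pct_change_vs_a"] == pytest.approx(40.0)

    def test_missing_control_rejected(self):
        reps = [self._rep("a", 1, 1, 0.1), self._rep("b", 2, 2, 0.2)]
        with pytest.raises(M.UndefinedComparisonError):
            M.comparison_table(reps, "zz")

    def test_report_validates_ranges(self):
        with pytest.raises(Exception):
            M.MetricsReport(scenario="x", peak_velocity=-1.0, mean_tpg=0.0,
                            rt_mean=0.0, rt_max=0.0, pct_vol_rt_gt_02=0.0)

    def test_mmhg_conversion(self):
        r = self._rep("a", 1.0, 133.322, 0.1)
        assert r.mean_tpg_mmhg == pytest.approx(1.0)
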