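"""Geometry synthesis: watertightness, tagging, analytic volumes, scenarios."""

import numpy as np
import pytest
from scipy.integrate import simpson

from aortaflow import geometry as G
from aortaflow.bcs import ValveSpec
from aortaflow.geometry import (FacetTag, FunnelInsert, ParameterError,
                                RootParameters, RootProfile, Scenario,
                                analytic_lumen_volume, apply_scenario,
                                build_fixture_mesh, build_root_mesh)


def brute_force_profile_volume(params, mode, n=20001):
    """Independent quadrature of the revolved/extruded lumen profile."""
    prof = RootProfile(params)
    z = np.linspace(0.0, prof.length, n)
    r = prof.radius(z)
    area = np.pi * r ** 2 if mode == "3d" else 2.0 * r
    if params.tavr_insert is not None:
        m = (z > prof.z_funnel_bot) & (z < prof.z_valve)
        xf = prof.funnel_radius(z[m])
        area[m] = np.pi * xf ** 2 if mode == "3d" else 2.0 * xf
    return float(simpson(area, x=z))


class TestRootMesh:
    @pytest.mark.parametrize("scenario,valve_d,mode,edge", [
        ("baseline", 23.0, "2d", 1.5),
        ("yaae", 29.0, "2d", 1.5),
        ("tavr_in_savr", 23.0, "2d", 1.5),
        ("baseline", 23.0, "3d", 2.5),
        ("tavr_in_savr", 23.0, "3d", 2.5),
    ])
    def test_volume_matches_analytic_profile(self, scenario, valve_d, mode,
                                             edge):
        params = apply_scenario(RootParameters(), scenario, ValveSpec(valve_d))
        mesh = build_root_mesh(params, edge, mode)
        mesh.validate()
        oracle = brute_force_profile_volume(params, mode)
        assert mesh.volume == pytest.approx(oracle, rel=0.05)
        # the package's own quadrature agrees with the independent oracle
        assert analytic_lumen_volume(params, mode) == pytest.approx(
            oracle, rel=1e-4)

    def test_boundary_single_tag_coverage(self, root_mesh_2d):
        """Every boundary facet of the cell complex carries exactly one tag."""
        uniq, counts = root_mesh_2d.boundary_census()
        boundary = {tuple(f) for f in np.sort(uniq[counts == 1], axis=1)}
        tagged = {tuple(f) for f in np.sort(root_mesh_2d.facets, axis=1)}
        assert boundary <= tagged
        assert counts.max() == 2

    def test_all_tag_classes_present(self, root_mesh_2d):
        tags = set(root_mesh_2d.facet_tags)
        assert {int(t) for t in (FacetTag.INLET, FacetTag.OUTLET,
                                 FacetTag.WALL, FacetTag.CORONARY_L,
                                 FacetTag.CORONARY_R, FacetTag.VALVE_ORIFICE,
                                 FacetTag.VALVE_ANNULUS)} <= tags

    def test_valve_plane_is_planar_cross_section(self, root_mesh_2d):
        mesh = root_mesh_2d
        nodes = mesh.nodes_with_tag(FacetTag.VALVE_ORIFICE,
                                    FacetTag.VALVE_ANNULUS)
        z = mesh.vertices[nodes, mesh.axis]
        assert np.allclose(z, mesh.meta["z_valve"])
        # the tagged facets span the full lumen width at the plane
        xs = mesh.vertices[nodes, 0]
        prof_r = RootParameters().annulus_diameter / 2.0
        assert xs.min() == pytest.approx(-prof_r, abs=1e-9)
        assert xs.max() == pytest.approx(prof_r, abs=1e-9)

    def test_volume_monotone_in_enlargement(self):
        vols = []
        for ef in (1.0, 1.15, 1.3):
            params = RootParameters(enlargement_factor=ef, goa_diameter=17.0)
            vols.append(build_root_mesh(params, 1.8, "2d").volume)
        assert vols[0] < vols[1] < vols[2]

    def test_insert_subtracts_volume(self):
        valve = ValveSpec(23.0)
        base = apply_scenario(RootParameters(), "baseline", valve)
        tavr = apply_scenario(RootParameters(), "tavr_in_savr", valve)
        vb = build_root_mesh(base, 1.6, "2d").volume
        vt = build_root_mesh(tavr, 1.6, "2d").volume
        assert vt < vb

    def test_deterministic_regeneration(self):
        params = RootParameters(goa_diameter=17.0)
        m1 = build_root_mesh(params, 1.7, "2d", seed=3)
        m2 = build_root_mesh(params, 1.7, "2d", seed=3)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.cells, m2.cells)
        assert np.array_equal(m1.facet_tags, m2.facet_tags)

    def test_coarse_edge_rejected(self):
        with pytest.raises(ParameterError):
            build_root_mesh(RootParameters(), 23.0, "2d")

    def test_throat_larger_than_orifice_rejected(self):
        with pytest.raises(ParameterError):
            FunnelInsert(inlet_diameter=17.0, throat_diameter=18.0)

    def test_short_aorta_rejected(self):
        with pytest.raises(ParameterError):
            RootParameters(aorta_length=25.0)


class TestScenarios:
    def test_yaae_scales_annulus_by_valve_ratio(self):
        params = apply_scenario(RootParameters(annulus_diameter=23.0),
                                Scenario.YAAE, ValveSpec(29.0))
        assert params.enlargement_factor == pytest.approx(29.0 / 23.0)
        assert params.effective_annulus_diameter == pytest.approx(29.0)
        assert params.resolved_goa_diameter == pytest.approx(23.0)

    def test_baseline_identity(self):
        base = RootParameters()
        out = apply_scenario(base, Scenario.BASELINE, ValveSpec(23.0))
        assert out.enlargement_factor == base.enlargement_factor
        assert out.tavr_insert is None
        assert out.annulus_diameter == base.annulus_diameter

    def test_tavr_throat_reduces_orifice_area_20pct(self):
        out = apply_scenario(RootParameters(), Scenario.TAVR_IN_SAVR,
                             ValveSpec(23.0))
        goa = 17.0
        area_ratio = (out.tavr_insert.throat_diameter / goa) ** 2
        assert area_ratio == pytest.approx(0.80, rel=1e-12)
        assert out.tavr_insert.axial_offset == 4.0

    def test_yaae_underscaled_enlargement_warns(self):
        params = RootParameters(enlargement_factor=1.1)
        with pytest.warns(UserWarning):
            out = apply_scenario(params, Scenario.YAAE, ValveSpec(29.0))
        assert out.enlargement_factor == pytest.approx(29.0 / 23.0)


class TestFixtures:
    def test_pipe_has_exactly_three_tag_classes(self, pipe_mesh):
        assert set(pipe_mesh.facet_tags) == {int(FacetTag.INLET),
                                             int(FacetTag.OUTLET),
                                             int(FacetTag.WALL)}
        assert pipe_mesh.volume == pytest.approx(np.pi * 4.0 * 20.0, rel=0.05)

    def test_cavity_is_closed(self, cavity_mesh):
        assert set(cavity_mesh.facet_tags) == {int(FacetTag.WALL)}
        uniq, counts = cavity_mesh.boundary_census()
        assert (counts == 1).sum() == len(cavity_mesh.facets)

    def test_channel_facets_match_boundary_edge_recount(self, channel_mesh):
        """Brute-force boundary-edge enumeration as the oracle."""
        cells = channel_mesh.cells
        from collections import Counter
        edges = Counter()
        for tri in cells:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                edges[tuple(sorted((tri[a], tri[b])))] += 1
        boundary = {e for e, c in edges.items() if c == 1}
        tagged = {tuple(sorted(f)) for f in channel_mesh.facets}
        assert boundary == tagged

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ParameterError):
            build_fixture_mesh("pipe", (0.0, 20.0), 0.5)


class TestMeshIO:
    def test_msh_roundtrip(self, tmp_path, root_mesh_2d):
        from aortaflow import io as aio
        paths = aio.save_mesh(tmp_path, "m", root_mesh_2d)
        back = aio.read_msh(paths["msh"], paths["tags"])
        assert np.allclose(back.vertices, root_mesh_2d.vertices)
        assert np.array_equal(back.cells, root_mesh_2d.cells)
        a = sorted(map(tuple, np.sort(root_mesh_2d.facets, axis=1)))
        b = sorted(map(tuple, np.sort(back.facets, axis=1)))
        assert a == b
        assert back.meta["z_valve"] == root_mesh_2d.meta["z_valve"]

    def test_vtu_is_wellformed_xml(self, tmp_path, channel_mesh):
        from xml.etree import ElementTree
        from aortaflow import io as aio
        n = channel_mesh.vertices.shape[0]
        aio.write_vtu(tmp_path / "m.vtu", channel_mesh,
                      {"f": np.arange(n, dtype=float),
                       "v": np.ones((n, 2))})
        tree = ElementTree.parse(tmp_path / "m.vtu")
        piece = tree.getroot().find(".//Piece")
        assert int(piece.get("NumberOfPoints")) == n
        assert int(piece.get("NumberOfCells")) == channel_mesh.cells.shape[0]
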