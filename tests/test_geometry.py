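"""Mesh construction: analytic region volumes, conforming interfaces,
refinement behaviour and named sets."""

import numpy as np
import pytest

from cellindent.geometry import (
    GeometryParams,
    REGIONS,
    build_gel_domain,
    element_volumes,
    refine,
    region_measure,
    write_vtk,
)


def hemisphere_volume(d):
    return 2.0 / 3.0 * np.pi * (d / 2.0) ** 3


class TestVolumes:
    """Revolved region volumes against closed forms (2% at default mesh)."""

    def test_cell_volume(self, coarse_mesh, default_params):
        v_cell = region_measure(coarse_mesh, "nucleus") + region_measure(
            coarse_mesh, "cytoplasm"
        )
        assert v_cell == pytest.approx(hemisphere_volume(20.0), rel=0.02)

    def test_nucleus_volume(self, coarse_mesh):
        exact = 4.0 / 3.0 * np.pi * 3.0 * 3.0 * 4.0  # ellipsoid 6 x 8 um
        assert region_measure(coarse_mesh, "nucleus") == pytest.approx(exact, rel=0.02)

    def test_cytoplasm_volume(self, coarse_mesh):
        exact = hemisphere_volume(20.0) - 4.0 / 3.0 * np.pi * 36.0
        assert region_measure(coarse_mesh, "cytoplasm") == pytest.approx(exact, rel=0.02)

    def test_gel_volume(self, coarse_mesh):
        exact = np.pi * 225.0**2 * 300.0
        assert region_measure(coarse_mesh, "gel") == pytest.approx(exact, rel=0.02)

    def test_unknown_region_raises(self, coarse_mesh):
        with pytest.raises(KeyError):
            region_measure(coarse_mesh, "mitochondrion")

    def test_missing_region_raises(self):
        gel_only = build_gel_domain(resolution=1)
        with pytest.raises(KeyError):
            region_measure(gel_only, "nucleus")


class TestMeshStructure:
    def test_all_radii_nonnegative_and_axis_nodes_exist(self, coarse_mesh):
        assert coarse_mesh.nodes[:, 0].min() >= 0.0
        assert len(coarse_mesh.surface_sets["axis"]) > 0

    def test_positive_element_areas(self, coarse_mesh):
        assert element_volumes(coarse_mesh).min() > 0.0

    def test_every_element_has_one_region(self, coarse_mesh):
        assert set(np.unique(coarse_mesh.region)) == set(REGIONS.values())
        assert coarse_mesh.region.shape[0] == coarse_mesh.n_elems

    def test_conforming_interfaces_no_duplicate_nodes(self, coarse_mesh):
        """Tied contact by construction: coincident coordinates appear once."""
        seen = {}
        for i, (r, z) in enumerate(np.round(coarse_mesh.nodes, 9)):
            key = (r, z)
            assert key not in seen, f"duplicate node at {key}"
            seen[key] = i

    def test_cell_base_nodes_are_gel_top_nodes(self, coarse_mesh):
        """The cell base circle and the gel surface beneath it share node ids."""
        m = coarse_mesh
        cyto = m.elems[m.region_elems("cytoplasm")].ravel()
        gel = m.elems[m.region_elems("gel")].ravel()
        z = m.nodes[:, 1]
        r = m.nodes[:, 0]
        cell_base = set(int(n) for n in cyto if abs(z[n]) < 1e-9)
        gel_under = set(
            int(n) for n in gel if abs(z[n]) < 1e-9 and r[n] <= m.params.cell_radius + 1e-9
        )
        assert cell_base == gel_under

    def test_nucleus_thirds_partition_by_height(self, coarse_mesh):
        m = coarse_mesh
        p = m.params
        top = m.element_sets["nucleus_top_third"]
        bot = m.element_sets["nucleus_bottom_third"]
        assert len(top) > 0 and len(bot) > 0
        assert len(np.intersect1d(top, bot)) == 0
        zc_top = m.nodes[m.elems[top, :3], 1].mean(axis=1)
        zc_bot = m.nodes[m.elems[bot, :3], 1].mean(axis=1)
        assert zc_top.min() > p.nucleus_center_z + p.nucleus_b / 3.0
        assert zc_bot.max() < p.nucleus_center_z - p.nucleus_b / 3.0

    def test_surface_sets_on_their_faces(self, coarse_mesh):
        m, p = coarse_mesh, coarse_mesh.params
        assert np.allclose(m.nodes[m.surface_sets["gel_bottom"], 1], -p.gel_thickness)
        assert np.allclose(m.nodes[m.surface_sets["gel_lateral"], 0], p.gel_radius)
        assert np.allclose(m.nodes[m.surface_sets["gel_top_free"], 1], 0.0)


class TestRefinement:
    def test_factor_one_is_identity(self, coarse_mesh):
        assert refine(coarse_mesh, 1) is coarse_mesh

    def test_factor_two_quadruples_elements_preserves_volumes(self, coarse_mesh):
        fine = refine(coarse_mesh, 2)
        ratio = fine.n_elems / coarse_mesh.n_elems
        assert 3.0 < ratio < 5.5
        for region in ("nucleus", "cytoplasm", "gel"):
            v_c = region_measure(coarse_mesh, region)
            v_f = region_measure(fine, region)
            # both approach the analytic value; difference bounded by the
            # coarse-mesh tolerance
            assert abs(v_f - v_c) / v_f < 0.02

    def test_refined_sets_preserved(self, coarse_mesh):
        fine = refine(coarse_mesh, 2)
        assert set(fine.surface_sets) == set(coarse_mesh.surface_sets)
        assert set(fine.element_sets) == set(coarse_mesh.element_sets)


class TestParams:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            GeometryParams(nucleus_diam_vertical=25.0)  # does not fit in cell
        with pytest.raises(ValueError):
            GeometryParams(cell_diameter=-1.0)
        with pytest.raises(ValueError):
            GeometryParams(contact_disc_diameter=7.0)  # exceeds nucleus
        with pytest.raises(ValueError):
            GeometryParams(gel_radius=50.0)  # not a half-space proxy

    def test_derived_quantities(self, default_params):
        p = default_params
        assert p.cell_radius == 10.0
        assert p.nucleus_a == 3.0
        assert p.nucleus_b == 4.0
        assert p.nucleus_center_z == pytest.approx(4.5)


def test_vtk_export_roundtrip_header(tmp_path, coarse_mesh):
    path = tmp_path / "mesh.vtk"
    write_vtk(
        coarse_mesh,
        path,
        point_data={"uz": np.zeros(coarse_mesh.n_nodes)},
    )
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert any(line.startswith("POINTS") for line in text)
    assert any(line.startswith("CELL_DATA") for line in text)
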