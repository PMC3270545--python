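"""Meshes, reference elements, quadrature, and field evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wlsfem import (PointNotFoundError, build_box_mesh,
                    build_half_ellipsoid_mesh, evaluate_field, make_plane_frame,
                    split_interior_surface, write_vtk)
from wlsfem.geometry import gauss_points, shape_functions


class TestBoxMesh:
    def test_biquadratic_counts(self, unit_square_2x2):
        m = unit_square_2x2
        assert m.n_nodes == 25
        assert m.n_elements == 4
        np.testing.assert_allclose(m.element_sizes(), 0.5)

    def test_triquadratic_counts(self, unit_cube_1):
        assert unit_cube_1.n_nodes == 27
        assert unit_cube_1.n_elements == 1

    def test_nondimensional_tank(self):
        # 15.4 cm water tank scaled by the 2.2 cm jet diameter
        side = 15.4 / 2.2
        assert side == pytest.approx(7.0, abs=0.05)
        m = build_box_mesh([side] * 3, [2, 2, 2])
        assert m.volume() == pytest.approx(side ** 3, rel=1e-12)

    @pytest.mark.parametrize("bad,kw", [
        ("extent", dict(extent=[0.0, 1.0], resolution=[2, 2])),
        ("resolution", dict(extent=[1.0, 1.0], resolution=[2, 0])),
    ])
    def test_invalid_inputs_name_the_axis(self, bad, kw):
        with pytest.raises(ValueError, match="axis"):
            build_box_mesh(**kw)

    def test_all_faces_tagged_with_analytic_areas(self):
        m = build_box_mesh([2.0, 3.0, 4.0], [2, 1, 2])
        areas = {"left": 12.0, "right": 12.0, "front": 8.0, "back": 8.0,
                 "bottom": 6.0, "top": 6.0}
        assert set(m.boundary_tags) == set(areas)
        for tag, a in areas.items():
            assert m.facet_area(tag) == pytest.approx(a, rel=1e-12)
        assert m.check_boundary_partition()


class TestReferenceElement:
    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_partition_of_unity(self, dim, rng):
        pts = rng.uniform(-1, 1, size=(40, dim))
        N, dN = shape_functions(dim, pts)
        np.testing.assert_allclose(N.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(dN.sum(axis=1), 0.0, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=2),
           st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    def test_quadratic_completeness_property(self, point, coef):
        # any total-degree-2 polynomial is reproduced to machine precision
        m = build_box_mesh([2.0, 2.0], [1, 1], origin=[-1.0, -1.0])
        c = np.asarray(coef)
        poly = lambda x: (c[0] + c[1] * x[..., 0] + c[2] * x[..., 1]
                          + c[3] * x[..., 0] ** 2 + c[4] * x[..., 1] ** 2
                          + c[5] * x[..., 0] * x[..., 1])
        val, _ = evaluate_field(m, poly(m.nodes), np.asarray(point))
        scale = 1.0 + np.abs(c).sum()
        assert abs(val - poly(np.asarray(point))) < 1e-12 * scale

    @pytest.mark.parametrize("dim", [2, 3])
    def test_gauss_rule_integrates_quintics(self, dim):
        pts, w = gauss_points(dim, 3)
        # int_{-1}^{1} x^5 dx = 0 ; int x^4 = 2/5 per direction
        assert w @ pts[:, 0] ** 5 == pytest.approx(0.0, abs=1e-14)
        assert w @ pts[:, 0] ** 4 == pytest.approx(0.4 * 2 ** (dim - 1), rel=1e-13)


class TestFieldEvaluation:
    def test_quadratic_reproduced_exactly(self, unit_square_2x2, rng):
        m = unit_square_2x2
        f = m.nodes[:, 0] ** 2 + 2 * m.nodes[:, 0] * m.nodes[:, 1]
        for _ in range(5):
            p = rng.uniform(0.05, 0.95, 2)
            val, grad = evaluate_field(m, f, p)
            assert val == pytest.approx(p[0] ** 2 + 2 * p[0] * p[1], abs=1e-12)
            np.testing.assert_allclose(
                grad, [2 * p[0] + 2 * p[1], 2 * p[0]], atol=1e-11)

    def test_constant_field(self, unit_cube_1):
        f = np.full(27, 3.7)
        val, grad = evaluate_field(unit_cube_1, f, [0.3, 0.6, 0.2])
        assert val == pytest.approx(3.7, abs=1e-13)
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_cubic_interpolation_error_third_order(self, rng):
        # nodal x^3 on h and h/2 meshes: error drops by ~8
        errs = []
        for n in (2, 4):
            m = build_box_mesh([1.0, 1.0], [n, n])
            f = m.nodes[:, 0] ** 3
            pts = rng.uniform(0.1, 0.9, size=(30, 2))
            e = max(abs(evaluate_field(m, f, p)[0] - p[0] ** 3) for p in pts)
            errs.append(e)
        assert errs[0] < 0.02  # C h^3 bound with h = 0.5
        assert errs[0] / errs[1] > 4.0

    def test_point_outside_is_a_distinct_error(self, unit_square_2x2):
        with pytest.raises(PointNotFoundError):
            evaluate_field(unit_square_2x2, unit_square_2x2.nodes[:, 0], [2.5, 0.5])


@pytest.fixture(scope="module")
def lv_mesh():
    return build_half_ellipsoid_mesh([1.0, 1.0, 1.5], 3)


class TestHalfEllipsoid:

    def test_tag_partition(self):
        hemi = build_half_ellipsoid_mesh([1.0, 1.0, 1.0], 2)
        assert hemi.primary_tags == {"base", "wall"}
        assert hemi.check_boundary_partition()

    def test_volume_close_to_closed_form(self, lv_mesh):
        exact = 2.0 / 3.0 * np.pi * 1.0 * 1.0 * 1.5
        assert abs(lv_mesh.volume() - exact) / exact < 0.05

    def test_positive_jacobians(self, lv_mesh):
        assert lv_mesh.check_jacobians() > 0

    def test_inlet_outlet_disjoint_subpatches(self, lv_mesh):
        inlet = {tuple(sorted(f.nodes)) for f in lv_mesh.boundary_tags["inlet"]}
        outlet = {tuple(sorted(f.nodes)) for f in lv_mesh.boundary_tags["outlet"]}
        base = {tuple(sorted(f.nodes)) for f in lv_mesh.boundary_tags["base"]}
        assert inlet and outlet
        assert not inlet & outlet
        assert inlet <= base and outlet <= base

    def test_base_is_flat_disk(self, lv_mesh):
        for f in lv_mesh.boundary_tags["base"]:
            assert np.all(np.abs(lv_mesh.nodes[f.nodes][:, 2]) < 1e-12)

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError):
            build_half_ellipsoid_mesh([1.0, 0.0, 1.0], 2)


class TestPlaneFrame:
    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            make_plane_frame([0, 0, 0], [0, 0, 0])  # zero normal -> nan
        f = make_plane_frame([0, 0, 0], [0, 0, 2.0])
        assert f.e1 @ f.e2 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.cross(f.e1, f.e2), f.normal, atol=1e-12)

    def test_2d_frame_degenerates_to_line(self):
        f = make_plane_frame([1.0, 2.0], [1.0, 0.0])
        assert f.e2 is None
        pts = f.to_world(np.array([[0.5, 0.0], [-0.5, 0.0]]))
        np.testing.assert_allclose(pts[:, 0], 1.0, atol=1e-14)


class TestFlapSplit:
    def test_duplicated_nodes_and_tags(self):
        m = build_box_mesh([7.0, 7.0], [7, 7])
        s = split_interior_surface(m, 2.0, 3.0)
        # nodes strictly between wall and tip are doubled: 5 on the open line
        dup = s.metadata["flap"]["duplicates"]
        assert len(dup) == 5
        assert s.n_nodes == m.n_nodes + 5
        assert len(s.boundary_tags["flap_left"]) == 3
        assert len(s.boundary_tags["flap_right"]) == 3
        assert s.check_boundary_partition()

    def test_two_sides_have_independent_dofs(self):
        m = build_box_mesh([7.0, 7.0], [7, 7])
        s = split_interior_surface(m, 2.0, 3.0)
        left_nodes = {n for f in s.boundary_tags["flap_left"] for n in f.nodes}
        right_nodes = {n for f in s.boundary_tags["flap_right"] for n in f.nodes}
        shared = left_nodes & right_nodes
        # only the root (on the wall) and the tip remain shared
        ys = sorted(s.nodes[list(shared)][:, 1])
        assert len(shared) == 2
        assert ys[0] == pytest.approx(0.0) and ys[1] == pytest.approx(3.0)


@pytest.mark.parametrize("make", [
    lambda: build_box_mesh([2.0, 1.0], [2, 3]),
    lambda: build_half_ellipsoid_mesh([1.0, 1.0, 1.5], 2),
])
def test_quadratic_vtk_roundtrip_preserves_mesh_and_tags(tmp_path, make):
    from wlsfem import read_vtk, write_vtk_quadratic
    mesh = make()
    path = tmp_path / "mesh.vtk"
    write_vtk_quadratic(mesh, str(path), point_data={"x": mesh.nodes[:, 0]})
    back = read_vtk(str(path))
    assert back.dim == mesh.dim
    np.testing.assert_allclose(back.nodes, mesh.nodes, atol=1e-14)
    np.testing.assert_array_equal(back.elements, mesh.elements)
    assert set(back.boundary_tags) >= set(
        t for t, fs in mesh.boundary_tags.items() if fs)
    assert back.primary_tags == mesh.primary_tags
    for tag, fs in mesh.boundary_tags.items():
        if fs:
            assert back.facet_area(tag) == pytest.approx(mesh.facet_area(tag),
                                                         rel=1e-12)
    assert back.volume() == pytest.approx(mesh.volume(), rel=1e-12)


def test_vtk_roundtrip_is_readable_text(tmp_path, unit_square_2x2):
    m = unit_square_2x2
    path = tmp_path / "mesh.vtk"
    write_vtk(m, str(path), point_data={"f": m.nodes[:, 0],
                                        "v": m.nodes})
    text = path.read_text()
    assert "UNSTRUCTURED_GRID" in text
    assert f"POINTS {m.n_nodes}" in text
    assert "VECTORS v double" in text
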