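"""Plane splitting, cumulative measures, and equal-measure slicing."""

import numpy as np
import pytest

import remorph as rm
from oracles import ray_parity_volume
from remorph import shapes
from remorph.core import TriMesh


def make_torus(R=2.0, r=0.7, nu=48, nv=24):
    """Watertight torus around z: its z cross-sections are annuli,
    exercising the polygon-with-holes cap path."""
    verts = []
    for i in range(nu):
        th = 2 * np.pi * i / nu
        for j in range(nv):
            ph = 2 * np.pi * j / nv
            verts.append(
                [
                    (R + r * np.cos(ph)) * np.cos(th),
                    (R + r * np.cos(ph)) * np.sin(th),
                    r * np.sin(ph),
                ]
            )

    def vid(i, j):
        return (i % nu) * nv + (j % nv)

    faces = []
    for i in range(nu):
        for j in range(nv):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriMesh(np.array(verts), faces)


class TestSplitByPlane:
    def test_cube_capped_halves(self, cube):
        lo, up = rm.split_by_plane(cube, "z", 0.5, cap=True)
        assert rm.is_watertight(lo) and rm.is_watertight(up)
        assert rm.enclosed_volume(lo) == pytest.approx(0.5, rel=1e-12)
        assert rm.enclosed_volume(up) == pytest.approx(0.5, rel=1e-12)

    def test_cube_hollow_halves(self, cube):
        lo, up = rm.split_by_plane(cube, "z", 0.5, cap=False)
        # 4 half-sides (4 × 0.5) + one original cap (1.0)
        assert rm.surface_area(lo) == pytest.approx(3.0, rel=1e-12)
        assert rm.surface_area(up) == pytest.approx(3.0, rel=1e-12)
        assert not rm.is_watertight(lo)

    def test_non_cap_area_conserved(self, tube):
        lo, up = rm.split_by_plane(tube, "z", 3.3, cap=False)
        assert rm.surface_area(lo) + rm.surface_area(up) == pytest.approx(
            rm.surface_area(tube), rel=1e-12
        )

    def test_plane_through_vertices_no_degenerate_faces(self, sphere):
        """The 64×32 sphere has a vertex ring exactly at z = 0."""
        lo, up = rm.split_by_plane(sphere, "z", 0.0, cap=True)
        assert rm.is_watertight(lo) and rm.is_watertight(up)
        from remorph.core import face_areas

        assert face_areas(lo).min() > 0
        assert face_areas(up).min() > 0
        assert rm.enclosed_volume(lo) == pytest.approx(
            rm.enclosed_volume(sphere) / 2, rel=1e-9
        )

    def test_annular_cross_section_caps(self):
        torus = make_torus()
        lo, up = rm.split_by_plane(torus, "z", 0.1, cap=True)
        assert rm.is_watertight(lo) and rm.is_watertight(up)
        assert rm.enclosed_volume(lo) + rm.enclosed_volume(up) == pytest.approx(
            rm.enclosed_volume(torus), rel=1e-12
        )

    def test_outside_extent_rejected(self, cube):
        with pytest.raises(rm.SliceError):
            rm.split_by_plane(cube, "z", 1.5, cap=False)
        with pytest.raises(rm.SliceError):
            rm.split_by_plane(cube, "z", 0.0, cap=False)


class TestCumulativeMeasure:
    def test_cylinder_volume_fraction(self, cylinder):
        total = rm.enclosed_volume(cylinder)
        got = rm.cumulative_measure(cylinder, "V", "z", 3.0)
        assert got == pytest.approx(0.3 * total, rel=1e-9)

    @pytest.mark.parametrize("n_sides", [16, 48])
    @pytest.mark.parametrize("c", [0.2, 0.5, 0.77])
    def test_cone_scaling_law_any_tessellation(self, n_sides, c):
        """V(≤c) = V_total · (1 − (1−c)³) holds exactly for every
        tessellation of the cone (similar-triangles scaling)."""
        cone = shapes.make_cone(1.0, 1.0, n_sides)
        total = rm.enclosed_volume(cone)
        got = rm.cumulative_measure(cone, "V", "z", c)
        assert got == pytest.approx(total * (1 - (1 - c) ** 3), rel=1e-9)

    def test_cone_matches_split_brute_force(self, cone):
        """Cross-check the analytic accumulation against actually
        splitting the mesh and measuring the capped lower piece."""
        c = 0.37
        lower, _ = rm.split_by_plane(cone, "z", c, cap=True)
        assert rm.cumulative_measure(cone, "V", "z", c) == pytest.approx(
            rm.enclosed_volume(lower), rel=1e-9
        )

    def test_open_tube_lateral_fraction(self):
        open_cyl = shapes.make_cylinder(1.0, 1.0, 32, capped=False)
        total = rm.surface_area(open_cyl)
        got = rm.cumulative_measure(open_cyl, "SA", "z", 0.25)
        assert got == pytest.approx(0.25 * total, rel=1e-9)

    def test_volume_mode_requires_watertight(self, cube):
        open_cube = rm.TriMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(rm.NotWatertightError):
            rm.cumulative_measure(open_cube, "V", "z", 0.5)

    def test_monotone_in_c(self, tube):
        cs = np.linspace(0.5, 9.5, 19)
        vals = [rm.cumulative_measure(tube, "SA", "z", c) for c in cs]
        assert np.all(np.diff(vals) >= 0)


class TestSliceEqual:
    def test_cylinder_volume_cuts_uniform(self, cylinder):
        res = rm.slice_equal(cylinder, rm.SliceSpec("V", 4, "z", 1e-5))
        assert np.allclose(res.cut_coordinates, [2.5, 5.0, 7.5], atol=1e-3)
        assert all(rm.is_watertight(s) for s in res.segments)

    def test_cone_half_volume_cut_closed_form(self):
        """Equal-volume bisection of a cone cuts at z = 1 − 2^(−1/3),
        independent of tessellation; cross-checked by Monte Carlo."""
        for n_sides in (16, 64):
            cone = shapes.make_cone(1.0, 1.0, n_sides)
            res = rm.slice_equal(cone, rm.SliceSpec("V", 2, "z", 1e-7))
            assert res.cut_coordinates[0] == pytest.approx(
                1 - 2 ** (-1 / 3), abs=1e-4
            )
        est, se = ray_parity_volume(res.segments[0], n_samples=100_000, seed=5)
        assert abs(res.measures[0] - est) <= 3 * se

    def test_capped_cylinder_sa_symmetry(self):
        cyl = shapes.make_cylinder(1.0, 1.0, 32, capped=True)
        res = rm.slice_equal(cyl, rm.SliceSpec("SA", 2, "z", 1e-6))
        assert res.cut_coordinates[0] == pytest.approx(0.5, abs=1e-5)

    def test_open_tube_sa_cuts_uniform(self):
        open_cyl = shapes.make_cylinder(1.0, 1.0, 32, capped=False)
        res = rm.slice_equal(open_cyl, rm.SliceSpec("SA", 5, "z", 1e-6))
        assert np.allclose(
            res.cut_coordinates, [0.2, 0.4, 0.6, 0.8], atol=1e-5
        )

    @pytest.mark.parametrize("margin", [1e-3, 1e-5])
    @pytest.mark.parametrize("mode", ["SA", "V"])
    def test_equal_measure_guarantee(self, tube, mode, margin):
        res = rm.slice_equal(tube, rm.SliceSpec(mode, 5, "z", margin))
        assert res.achieved_max_relative_deviation <= margin

    def test_volume_conservation(self, tube):
        res = rm.slice_equal(tube, rm.SliceSpec("V", 5, "z", 1e-4))
        total = sum(rm.enclosed_volume(s) for s in res.segments)
        assert total == pytest.approx(rm.enclosed_volume(tube), rel=1e-9)

    def test_area_conservation_hollow(self, tube):
        res = rm.slice_equal(tube, rm.SliceSpec("SA", 5, "z", 1e-4))
        total = sum(rm.surface_area(s) for s in res.segments)
        assert total == pytest.approx(rm.surface_area(tube), rel=1e-9)

    def test_watertightness_closure(self, tube):
        res = rm.slice_equal(tube, rm.SliceSpec("V", 6, "z", 1e-4))
        assert all(rm.is_watertight(s) for s in res.segments)

    def test_cut_monotonicity_and_count(self, tube):
        res = rm.slice_equal(tube, rm.SliceSpec("SA", 7, "z", 1e-4))
        assert len(res.segments) == 7
        assert np.all(np.diff(res.cut_coordinates) > 0)

    def test_cap_areas_reported_separately(self, cylinder):
        res = rm.slice_equal(cylinder, rm.SliceSpec("V", 4, "z", 1e-5))
        assert res.cap_areas is not None
        # interior segments have two caps of the cylinder's section area
        section = shapes.polygon_area(64, 1.0)
        assert res.cap_areas[1] == pytest.approx(2 * section, rel=1e-3)
        # hollow per-segment area + caps equals the measured total area
        for seg, cap_a in zip(res.segments, res.cap_areas):
            assert rm.surface_area(seg) >= cap_a

    def test_volume_mode_open_mesh_rejected(self, cube):
        open_cube = rm.TriMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(rm.NotWatertightError):
            rm.slice_equal(open_cube, rm.SliceSpec("V", 3, "z", 1e-4))

    def test_sa_mode_accepts_open_mesh(self, cube):
        open_cyl = shapes.make_cylinder(1.0, 2.0, 16, capped=False)
        res = rm.slice_equal(open_cyl, rm.SliceSpec("SA", 3, "z", 1e-5))
        assert len(res.segments) == 3

    def test_bad_spec_rejected(self):
        with pytest.raises(rm.SliceError):
            rm.SliceSpec("XX", 3)
        with pytest.raises(rm.SliceError):
            rm.SliceSpec("SA", 1)
        with pytest.raises(rm.SliceError):
            rm.SliceSpec("SA", 3, error_margin=0)

    def test_x_axis_slicing(self, sphere):
        res = rm.slice_equal(sphere, rm.SliceSpec("V", 3, "x", 1e-4))
        assert all(rm.is_watertight(s) for s in res.segments)
        assert res.achieved_max_relative_deviation <= 1e-4
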