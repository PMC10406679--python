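"""Core mesh model and morphometrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import remorph as rm
from oracles import ray_parity_volume, to_trimesh
from remorph import shapes


def single_triangle():
    return rm.TriMesh(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        [[0, 1, 2]],
    )


class TestSurfaceArea:
    def test_closed_forms(self, cube, sphere, cylinder, cone):
        assert rm.surface_area(cube) == pytest.approx(6.0, abs=1e-12)
        assert rm.surface_area(single_triangle()) == pytest.approx(0.5, abs=1e-15)
        n = 64
        lat = 2 * n * 1.0 * np.sin(np.pi / n) * 10.0
        cap = shapes.polygon_area(n, 1.0)
        assert rm.surface_area(cylinder) == pytest.approx(lat + 2 * cap, rel=1e-12)
        # continuous limit within 1% at 64x32
        assert rm.surface_area(sphere) == pytest.approx(4 * np.pi, rel=0.01)

    def test_box_1_2_3(self):
        box = shapes.make_box((1, 2, 3))
        assert rm.surface_area(box) == pytest.approx(22.0, abs=1e-12)
        assert rm.enclosed_volume(box) == pytest.approx(6.0, abs=1e-12)

    def test_orientation_independent(self, cube):
        flipped = rm.TriMesh(cube.vertices, cube.faces[:, ::-1])
        assert rm.surface_area(flipped) == pytest.approx(rm.surface_area(cube))

    def test_empty_mesh_rejected(self):
        empty = rm.TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(rm.EmptyMeshError):
            rm.surface_area(empty)

    def test_agrees_with_trimesh(self, tube):
        assert rm.surface_area(tube) == pytest.approx(to_trimesh(tube).area, rel=1e-12)


class TestEnclosedVolume:
    def test_closed_forms(self, cube, sphere, cylinder, cone):
        assert rm.enclosed_volume(cube) == pytest.approx(1.0, abs=1e-12)
        cap = shapes.polygon_area(64, 1.0)
        assert rm.enclosed_volume(cylinder) == pytest.approx(cap * 10.0, rel=1e-12)
        assert rm.enclosed_volume(cone) == pytest.approx(cap / 3.0, rel=1e-12)
        assert rm.enclosed_volume(sphere) == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_open_surface_rejected(self, cube):
        open_cube = rm.TriMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(rm.NotWatertightError, match="open"):
            rm.enclosed_volume(open_cube)

    def test_mixed_orientation_rejected(self, cube):
        faces = cube.faces.copy()
        faces[0] = faces[0, ::-1]
        with pytest.raises(rm.InconsistentOrientationError):
            rm.enclosed_volume(rm.TriMesh(cube.vertices, faces))

    def test_globally_flipped_magnitude(self, cube):
        flipped = rm.TriMesh(cube.vertices, cube.faces[:, ::-1])
        assert rm.enclosed_volume(flipped) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_trimesh(self, tube):
        assert rm.enclosed_volume(tube) == pytest.approx(
            abs(to_trimesh(tube).volume), rel=1e-12
        )

    @pytest.mark.parametrize(
        "maker",
        [
            shapes.make_box,
            lambda: shapes.make_cylinder(1.0, 10.0, 32),
            lambda: shapes.make_cone(1.0, 1.0, 32),
            lambda: shapes.make_uv_sphere(1.0, 32, 16),
            lambda: shapes.make_tube(
                lambda z: 1 + 0.5 * np.sin(2 * np.pi * z / 10), 10.0, 32, 24
            ),
        ],
        ids=["box", "cylinder", "cone", "sphere", "tube"],
    )
    def test_monte_carlo_ray_parity_oracle(self, maker):
        """Volume agrees with a 1e5-sample inside/outside oracle to 3 SE."""
        mesh = maker()
        est, se = ray_parity_volume(mesh, n_samples=100_000, seed=42)
        assert abs(rm.enclosed_volume(mesh) - est) <= 3 * se


class TestScalingLaws:
    @given(s=st.floats(0.1, 10.0))
    def test_scale_law(self, s):
        cube = shapes.make_box()
        scaled = cube.scaled(s)
        assert rm.surface_area(scaled) == pytest.approx(6 * s**2, rel=1e-12)
        assert rm.enclosed_volume(scaled) == pytest.approx(s**3, rel=1e-12)

    @given(
        t=st.tuples(
            st.floats(-100, 100), st.floats(-100, 100), st.floats(-100, 100)
        )
    )
    def test_translation_invariance(self, t):
        cyl = shapes.make_cylinder(1.0, 10.0, 16)
        moved = cyl.translated(t)
        assert rm.surface_area(moved) == pytest.approx(
            rm.surface_area(cyl), rel=1e-9
        )
        assert rm.enclosed_volume(moved) == pytest.approx(
            rm.enclosed_volume(cyl), rel=1e-9
        )


class TestComponents:
    def test_two_cubes(self, two_cubes):
        comps = rm.connected_components(two_cubes)
        assert len(comps) == 2
        assert [c.n_faces for c in comps] == [12, 12]

    def test_single_component_identity(self, cube):
        (comp,) = rm.connected_components(cube)
        assert comp.n_faces == cube.n_faces
        assert rm.surface_area(comp) == pytest.approx(rm.surface_area(cube))

    def test_cube_plus_isolated_triangle(self, cube):
        tri = single_triangle().translated((5, 5, 5))
        mesh = rm.merge([cube, tri])
        comps = rm.connected_components(mesh)
        assert sorted(c.n_faces for c in comps) == [1, 12]

    def test_partition_covers_faces(self, two_cubes):
        comps = rm.connected_components(two_cubes)
        assert sum(c.n_faces for c in comps) == two_cubes.n_faces

    def test_agrees_with_trimesh(self, two_cubes):
        tm_parts = to_trimesh(two_cubes).split(only_watertight=False)
        assert len(tm_parts) == len(rm.connected_components(two_cubes))


class TestKeepLargest:
    def test_by_area_not_count(self):
        big = shapes.make_box()
        small = shapes.make_box((0.1, 0.1, 0.1), origin=(5, 5, 5))
        kept = rm.keep_largest_component(rm.merge([big, small]))
        assert rm.surface_area(kept) == pytest.approx(6.0)

    def test_identity_on_single(self, cube):
        kept = rm.keep_largest_component(cube)
        assert rm.surface_area(kept) == pytest.approx(6.0)
        assert kept.n_faces == 12

    def test_tie_keeps_first(self):
        mesh = shapes.make_two_component()
        kept = rm.keep_largest_component(mesh)
        # the cube containing face 0 starts at the origin
        assert kept.vertices[:, 0].min() == pytest.approx(0.0)
        assert kept.vertices[:, 0].max() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(rm.EmptyMeshError):
            rm.keep_largest_component(
                rm.TriMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
            )


class TestBoundingBox:
    def test_cube_tie_rule(self, cube):
        bb = rm.bounding_box(cube)
        assert np.allclose(bb.extent, [1, 1, 1])
        assert bb.longest_axis == "x"

    def test_cylinder_longest_z(self):
        cyl = shapes.make_cylinder(1.0, 4.0, 16)
        bb = rm.bounding_box(cyl)
        assert np.allclose(bb.extent, [2, 2, 4])
        assert bb.longest_axis == "z"

    def test_single_point_degenerate(self):
        bb = rm.bounding_box(rm.PointCloud([[1.0, 2.0, 3.0]]))
        assert np.allclose(bb.extent, 0)
        assert bb.longest_axis == "x"

    def test_empty_rejected(self):
        with pytest.raises(rm.EmptyMeshError):
            rm.bounding_box(np.zeros((0, 3)))


class TestDecimate:
    def test_identity_at_ratio_one(self, sphere):
        assert rm.decimate(sphere, 1.0) is sphere

    def test_sphere_quality_contract(self, sphere):
        """SA and V drift < 2% at ratio 0.25; watertight preserved."""
        dec = rm.decimate(sphere, 0.25)
        assert dec.n_faces <= int(np.ceil(0.25 * sphere.n_faces))
        assert rm.is_watertight(dec)
        assert abs(dec.area - sphere.area) / sphere.area < 0.02
        assert abs(dec.volume - sphere.volume) / sphere.volume < 0.02

    @pytest.mark.parametrize("ratio", [0.0, -0.5, 1.5])
    def test_bad_ratio_rejected(self, cube, ratio):
        with pytest.raises(rm.RemorphError):
            rm.decimate(cube, ratio)


class TestMeasure:
    def test_cube_report(self, cube):
        m = rm.measure(cube)
        assert m.surface_area == pytest.approx(6.0)
        assert m.volume == pytest.approx(1.0)
        assert m.watertight and m.n_components == 1
        assert m.n_vertices == 8 and m.n_faces == 12

    def test_open_mesh_volume_unavailable(self, cube):
        m = rm.measure(rm.TriMesh(cube.vertices, cube.faces[:-1]))
        assert m.volume is None and not m.watertight
        assert m.as_dict()["volume"] == "unavailable"
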