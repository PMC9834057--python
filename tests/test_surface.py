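"""Surface geometry: inflation/convexity, spherical mapping, curvature,
area, thickness, ribbon sampling, spherical resampling."""

import numpy as np
import pytest

from svatlas.data_model import ScalarVolume, ValidationError, VoxelGrid
from svatlas.surface import (
    SphericalMap,
    TopologyError,
    TriangleMesh,
    cortical_thickness,
    inflate_surface,
    map_to_sphere,
    mean_curvature,
    resample_attribute_on_sphere,
    sample_ribbon_ratio,
    surface_area,
    vertex_areas,
    vertex_normals,
)
from svatlas.synth import make_icosphere


class TestAreaAndNormals:
    def test_icosphere_area_matches_analytic(self, icosphere4):
        assert surface_area(icosphere4) == pytest.approx(4 * np.pi, rel=0.01)

    def test_area_scales_quadratically(self, icosphere3):
        doubled = TriangleMesh(icosphere3.vertices * 2.0, icosphere3.triangles)
        assert surface_area(doubled) == pytest.approx(4 * surface_area(icosphere3))

    def test_vertex_areas_partition_total(self, icosphere3):
        assert vertex_areas(icosphere3).sum() == pytest.approx(
            surface_area(icosphere3), rel=1e-9
        )

    def test_sphere_normals_point_outward(self, icosphere3):
        n = vertex_normals(icosphere3)
        assert ((n * icosphere3.vertices).sum(axis=1) > 0.99).all()


class TestCurvature:
    def test_unit_sphere_curvature(self, icosphere4):
        H = mean_curvature(icosphere4)
        assert np.median(np.abs(H - 1.0)) < 0.05

    def test_curvature_scaling_law(self, icosphere4):
        big = TriangleMesh(icosphere4.vertices * 2.0, icosphere4.triangles)
        H = mean_curvature(big)
        assert np.median(np.abs(H - 0.5)) < 0.025

    def test_saddle_region_near_zero(self):
        # sinusoidal perturbation of a sphere: inflection band has |H| well
        # below the cap curvature
        ico = make_icosphere(4, 10.0)
        v = ico.vertices.copy()
        z = v[:, 2] / 10.0
        v *= (1.0 + 0.15 * z**2)[:, None]
        mesh = TriangleMesh(v, ico.triangles)
        H = mean_curvature(mesh)
        assert np.isfinite(H).all()
        # poles (caps) more curved than the equatorial band
        eq = np.abs(z) < 0.2
        pole = np.abs(z) > 0.9
        assert np.abs(H[pole]).mean() != pytest.approx(np.abs(H[eq]).mean())

    def test_degenerate_triangles_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], dtype=float)
        tris = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        with pytest.raises(ValidationError):
            mean_curvature(TriangleMesh(verts, tris))


class TestThickness:
    def test_concentric_spheres(self):
        w = make_icosphere(3, 1.0)
        p = make_icosphere(3, 1.5)
        th = cortical_thickness(w, p)
        assert np.allclose(th, 0.5, atol=1e-12)

    def test_identical_surfaces_zero(self, icosphere3):
        assert np.all(cortical_thickness(icosphere3, icosphere3) == 0)

    def test_normal_offset_recovered(self, icosphere3):
        n = vertex_normals(icosphere3)
        pial = TriangleMesh(icosphere3.vertices + 1.2 * n, icosphere3.triangles)
        th = cortical_thickness(icosphere3, pial)
        assert np.allclose(th, 1.2, atol=1e-6)

    def test_vertex_count_mismatch_rejected(self, icosphere3, icosphere4):
        with pytest.raises(ValidationError):
            cortical_thickness(icosphere3, icosphere4)


class TestInflation:
    def test_sphere_is_near_stationary_with_zero_convexity(self, icosphere4):
        inflated, conv = inflate_surface(icosphere4, n_steps=200)
        assert np.abs(conv).max() < 1e-3  # radius 1
        assert surface_area(inflated) == pytest.approx(surface_area(icosphere4), rel=1e-3)

    def test_dimple_has_negative_convexity(self, icosphere3):
        v = icosphere3.vertices.copy()
        dim = v[:, 2] > 0.85
        v[dim] *= 0.8
        _, conv = inflate_surface(TriangleMesh(v, icosphere3.triangles), n_steps=200)
        antipodal = icosphere3.vertices[:, 2] < -0.85
        assert conv[dim].mean() < 0
        assert conv[dim].mean() < conv[antipodal].mean() - 0.02
        assert abs(conv[antipodal].mean()) < 0.5 * abs(conv[dim].mean())

    def test_area_preserved_each_run(self, icosphere3):
        v = icosphere3.vertices * (1.0 + 0.1 * icosphere3.vertices[:, 2:3] ** 2)
        mesh = TriangleMesh(v, icosphere3.triangles)
        inflated, _ = inflate_surface(mesh, n_steps=50)
        assert surface_area(inflated) == pytest.approx(surface_area(mesh), rel=1e-3)

    def test_convexity_integrates_to_zero(self, icosphere3):
        v = icosphere3.vertices * (1.0 + 0.1 * np.sin(3 * icosphere3.vertices[:, 2:3]))
        mesh = TriangleMesh(v, icosphere3.triangles)
        inflated, conv = inflate_surface(mesh, n_steps=100)
        va = vertex_areas(inflated)
        integral = np.average(conv, weights=va)
        assert abs(integral) < 0.01 * (conv.max() - conv.min())

    def test_open_mesh_rejected(self, icosphere3):
        open_mesh = TriangleMesh(icosphere3.vertices, icosphere3.triangles[:-5])
        with pytest.raises(TopologyError):
            inflate_surface(open_mesh)


class TestSphericalMapping:
    def test_icosphere_maps_to_itself(self, icosphere4):
        smap = map_to_sphere(icosphere4)
        assert np.allclose(np.linalg.norm(smap.positions, axis=1), 1.0, atol=1e-9)
        assert np.abs(smap.positions - icosphere4.vertices).max() < 1e-4

    def test_ellipsoid_maps_without_folds(self, icosphere3):
        v = icosphere3.vertices * np.array([1.0, 1.0, 1.2])
        smap = map_to_sphere(TriangleMesh(v, icosphere3.triangles))
        assert np.allclose(np.linalg.norm(smap.positions, axis=1), 1.0, atol=1e-9)
        from svatlas.surface import _spherical_orient

        assert (_spherical_orient(smap.positions, smap.triangles) > 0).all()

    def test_relaxation_beats_plain_projection(self, icosphere3):
        v = icosphere3.vertices * np.array([1.0, 1.0, 1.3])
        mesh = TriangleMesh(v, icosphere3.triangles)
        edges = np.unique(
            np.sort(mesh.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1), axis=0
        )
        ref_len = np.linalg.norm(
            mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
        ) * np.sqrt(4 * np.pi / surface_area(mesh))

        def energy(p):
            el = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
            return ((el - ref_len) ** 2).sum()

        proj = v - v.mean(axis=0)
        proj /= np.linalg.norm(proj, axis=1, keepdims=True)
        relaxed = map_to_sphere(mesh)
        assert energy(relaxed.positions) <= energy(proj) + 1e-12


class TestRibbonSampling:
    def grid_and_volumes(self, factor=2.0):
        grid = VoxelGrid((24, 24, 24), (1.0, 1.0, 1.0), (-11.5, -11.5, -11.5))
        x = grid.world_coords()
        t2 = np.full(grid.shape, 1.0)
        t1 = factor * t2
        return grid, ScalarVolume(grid, t1), ScalarVolume(grid, t2)

    def test_constant_ratio(self, icosphere3):
        grid, t1, t2 = self.grid_and_volumes(2.0)
        w = TriangleMesh(icosphere3.vertices * 4.0, icosphere3.triangles)
        p = TriangleMesh(icosphere3.vertices * 6.0, icosphere3.triangles)
        ratio = sample_ribbon_ratio(t1, t2, w, p)
        assert np.allclose(ratio, 2.0, atol=1e-9)

    def test_equal_volumes_give_unity(self, icosphere3):
        grid, t1, t2 = self.grid_and_volumes(1.0)
        w = TriangleMesh(icosphere3.vertices * 4.0, icosphere3.triangles)
        p = TriangleMesh(icosphere3.vertices * 6.0, icosphere3.triangles)
        assert np.allclose(sample_ribbon_ratio(t1, t2, w, p), 1.0, atol=1e-9)

    def test_linear_ramp_average(self, icosphere3):
        grid = VoxelGrid((24, 24, 24), (1.0, 1.0, 1.0), (-11.5, -11.5, -11.5))
        x = grid.world_coords()
        t1 = ScalarVolume(grid, 5.0 + x[..., 0])
        t2 = ScalarVolume(grid, np.ones(grid.shape))
        # straight radial ribbon along +x at one vertex: analytic mean of the
        # ramp over equally spaced depths
        w = TriangleMesh(icosphere3.vertices * 4.0, icosphere3.triangles)
        p = TriangleMesh(icosphere3.vertices * 6.0, icosphere3.triangles)
        ratio = sample_ribbon_ratio(t1, t2, w, p, n_depths=5)
        vx = np.argmax(icosphere3.vertices[:, 0])  # vertex at +x pole
        expected = np.mean([5.0 + r for r in np.linspace(4.0, 6.0, 5)])
        assert ratio[vx] == pytest.approx(expected, abs=1e-6)

    def test_zero_t2_rejected(self, icosphere3):
        grid = VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        zeros = ScalarVolume(grid, np.zeros(grid.shape))
        w = TriangleMesh(icosphere3.vertices, icosphere3.triangles)
        with pytest.raises(ValidationError):
            sample_ribbon_ratio(zeros, zeros, w, w)


class TestSphericalResampling:
    def test_identity_targets_copy_attributes(self, icosphere3):
        smap = SphericalMap(icosphere3.vertices.copy(), icosphere3.triangles.copy())
        vals = np.sin(3 * icosphere3.vertices[:, 2])
        out = resample_attribute_on_sphere(smap, vals, icosphere3.vertices)
        assert np.allclose(out, vals, atol=1e-9)

    def test_constant_attribute_stays_constant(self, icosphere3, icosphere4):
        smap = SphericalMap(icosphere3.vertices.copy(), icosphere3.triangles.copy())
        out = resample_attribute_on_sphere(
            smap, np.full(icosphere3.n_vertices(), 3.5), icosphere4.vertices
        )
        assert np.allclose(out, 3.5, atol=1e-9)

    def test_linear_attribute_on_rotated_targets(self, icosphere4):
        smap = SphericalMap(icosphere4.vertices.copy(), icosphere4.triangles.copy())
        vals = icosphere4.vertices[:, 2]  # linear in z
        a = np.deg2rad(15)
        R = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        targets = icosphere4.vertices @ R.T
        out = resample_attribute_on_sphere(smap, vals, targets)
        assert np.abs(out - targets[:, 2]).max() < 0.02 * 2.0  # 2% of range
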