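"""SC-DEM: affine pre-alignment, forces, wave-equation solver, pair registration."""

import numpy as np
import pytest

from svatlas.data_model import (
    AffineTransform,
    DisplacementField,
    TissueProbMap,
    ValidationError,
    apply_affine_to_tissue_map,
    warp_tissue_map,
)
from svatlas.scdem import (
    DivergenceError,
    ScdemParams,
    SurfaceConstraint,
    _Splatter,
    affine_align,
    register_pair,
    solve_scdem,
    volumetric_force,
)
from svatlas.synth import GrowthModel, default_grid, make_phantom


@pytest.fixture(scope="module")
def tissue48():
    return make_phantom(
        12.0, GrowthModel(noise_sd=0.0), default_grid(48, 2.0), seed=4
    ).tissue


class TestParams:
    def test_cfl_violation_rejected(self):
        p = ScdemParams(alpha=1.0, dt=5.0)
        with pytest.raises(ValidationError):
            p.resolve_dt((2.0, 2.0, 2.0))

    def test_auto_dt_below_limit(self):
        p = ScdemParams(alpha=1.0)
        dt = p.resolve_dt((2.0, 2.0, 2.0))
        assert dt < p.cfl_limit((2.0, 2.0, 2.0))

    def test_for_grid_constructs_valid_dt(self):
        grid = default_grid(16, 2.0)
        p = ScdemParams.for_grid(grid, alpha=0.5)
        assert p.dt is not None and p.dt > 0

    def test_invalid_damping(self):
        with pytest.raises(ValidationError):
            ScdemParams(damping=1.0)


class TestAffineAlign:
    def test_identity_on_same_map(self, tissue48):
        aff = affine_align(tissue48, tissue48)
        assert np.abs(aff.matrix - np.eye(3)).max() < 1e-6
        assert np.abs(aff.translation).max() < 1e-6

    def test_translation_recovered(self, tissue48):
        t = np.array([3.0, 0.0, -2.0])
        true = AffineTransform(np.eye(3), t)
        moved = apply_affine_to_tissue_map(tissue48, true.inverse(), tissue48.grid)
        rec = affine_align(moved, tissue48)
        assert np.abs(rec.translation - t).max() < 0.1

    def test_isotropic_scale_recovered(self, tissue48):
        true = AffineTransform(np.eye(3) * 1.1, np.zeros(3))
        moved = apply_affine_to_tissue_map(tissue48, true.inverse(), tissue48.grid)
        rec = affine_align(moved, tissue48)
        assert np.abs(np.diag(rec.matrix) - 1.1).max() < 0.011

    def test_empty_foreground_rejected(self, small_grid):
        empty = TissueProbMap(small_grid, np.zeros(small_grid.shape + (3,)))
        with pytest.raises(ValidationError):
            affine_align(empty, empty)


class TestVolumetricForce:
    def test_zero_for_identical_maps(self, tissue48):
        f = volumetric_force(tissue48, tissue48)
        assert np.all(f == 0)

    def test_matches_literal_formula_on_toy_map(self, rng):
        grid = default_grid(8, 2.0)
        chans_m = np.clip(rng.uniform(0, 0.33, grid.shape + (3,)), 0, 1)
        chans_f = np.clip(rng.uniform(0, 0.33, grid.shape + (3,)), 0, 1)
        m = TissueProbMap(grid, chans_m)
        f = TissueProbMap(grid, chans_f)
        out = volumetric_force(m, f)
        expected = np.zeros(grid.shape + (3,))
        for c in range(3):
            resid = chans_m[..., c] - chans_f[..., c]
            g = np.gradient(chans_m[..., c], 2.0, 2.0, 2.0, edge_order=1)
            for ax in range(3):
                expected[..., ax] += resid * g[ax]
        assert np.abs(out - expected).max() < 1e-12

    def test_step_edge_force_points_toward_fixed_edge(self):
        grid = default_grid(16, 2.0)
        x = grid.world_coords()[..., 0]
        mov = np.zeros(grid.shape + (3,))
        fix = np.zeros(grid.shape + (3,))
        mov[..., 0] = 1.0 / (1.0 + np.exp(-(x - 2.0)))  # moving edge at +2mm
        fix[..., 0] = 1.0 / (1.0 + np.exp(-x))  # fixed edge at 0
        f = volumetric_force(TissueProbMap(grid, mov), TissueProbMap(grid, fix))
        # between the edges the mismatch force points from the moving edge
        # toward the fixed edge (negative x)
        band = (x > 0.0) & (x < 2.0)
        assert f[..., 0][band].mean() < 0

    def test_zero_where_moving_map_constant(self, rng):
        grid = default_grid(8, 2.0)
        mov = TissueProbMap(grid, np.full(grid.shape + (3,), 0.2))
        fix = TissueProbMap(grid, np.clip(rng.uniform(0, 0.33, grid.shape + (3,)), 0, 1))
        assert np.all(volumetric_force(mov, fix) == 0)


class TestSurfaceForce:
    def test_zero_when_field_matches_targets(self, small_grid):
        pts = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        disp = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        phi = DisplacementField(small_grid, np.zeros(small_grid.shape + (3,)))
        phi.vectors[...] = 0
        # build a field equal to the target at every voxel -> residual zero
        from svatlas.scdem import surface_force

        field = DisplacementField(small_grid, np.zeros(small_grid.shape + (3,)))
        c = SurfaceConstraint(pts, np.zeros_like(disp))
        out = surface_force([c], field, kernel_mm=4.0)
        assert np.all(out == 0)

    def test_single_vertex_gaussian_splat_matches_oracle(self, small_grid):
        from svatlas.scdem import surface_force

        pts = np.array([[1.0, -1.0, 0.5]])
        disp = np.array([[1.0, 0.0, 0.0]])
        kernel = 4.0
        field = DisplacementField.zeros(small_grid)
        out = surface_force([SurfaceConstraint(pts, disp)], field, kernel)
        # brute-force splat: w = exp(-d^2/2k^2); a single vertex never
        # saturates the weight sum, so the force decays with the Gaussian
        x = small_grid.world_coords()
        d2 = ((x - pts[0]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * kernel**2))
        expected = np.where(
            (d2 <= (3 * kernel) ** 2)[..., None], w[..., None] * disp[0], 0.0
        )
        assert np.abs(out - expected).max() < 1e-10
        # near the vertex the force approaches the full displacement
        nearest = np.unravel_index(np.argmin(d2), d2.shape)
        assert out[nearest][0] > 0.8

    def test_zero_beyond_support_radius(self, small_grid):
        from svatlas.scdem import surface_force

        kernel = 2.0
        pts = np.array([[0.0, 0.0, 0.0]])
        disp = np.array([[1.0, 1.0, 1.0]])
        out = surface_force(
            [SurfaceConstraint(pts, disp)], DisplacementField.zeros(small_grid), kernel
        )
        x = small_grid.world_coords()
        far = np.linalg.norm(x, axis=-1) > 3 * kernel + 1e-9
        assert np.all(out[far] == 0)

    def test_empty_constraints_warn_and_zero(self, small_grid, caplog):
        from svatlas.scdem import surface_force

        out = surface_force([], DisplacementField.zeros(small_grid), 2.0)
        assert np.all(out == 0)


class TestSolver:
    def test_identical_maps_stay_at_zero(self, tissue48):
        p = ScdemParams(alpha=0.2, beta=2.0, gamma=0.0, max_steps=50, force_tol=1e-9)
        phi = solve_scdem(tissue48, tissue48, None, p)
        assert np.abs(phi.vectors).max() < 1e-9

    def test_pure_elasticity_decays_perturbation(self, tissue48):
        rng = np.random.default_rng(0)
        grid = tissue48.grid
        from scipy.ndimage import gaussian_filter

        phi0 = rng.normal(0, 1.0, grid.shape + (3,))
        for c in range(3):
            phi0[..., c] = gaussian_filter(phi0[..., c], 2.0)
        p = ScdemParams(alpha=0.5, beta=0.0, gamma=0.0, damping=0.2, max_steps=100,
                        force_tol=0.0)
        out = solve_scdem(tissue48, tissue48, None, p, phi0=phi0)
        assert np.linalg.norm(out.vectors) < np.linalg.norm(phi0)

    def test_divergence_detected(self, tissue48):
        # absurd dt forced via explicit value below CFL of tiny alpha but
        # far above the force-stiffness limit
        p = ScdemParams(alpha=1e-6, beta=500.0, gamma=0.0, dt=20.0, damping=0.0,
                        max_steps=200, force_tol=1e-12)
        with pytest.raises(DivergenceError):
            solve_scdem(
                warp_tissue_map(
                    tissue48,
                    __import__("svatlas.synth", fromlist=["make_known_deformation"])
                    .make_known_deformation(tissue48.grid, 6.0, 12.0, seed=2),
                ),
                tissue48,
                None,
                p,
            )

    def test_stability_under_cfl(self, tissue48):
        from svatlas.synth import make_known_deformation

        truth = make_known_deformation(tissue48.grid, 6.0, 16.0, seed=3)
        moving = warp_tissue_map(tissue48, truth)
        p = ScdemParams(alpha=0.15, beta=8.0, gamma=0.0, damping=0.25, max_steps=150,
                        force_tol=1e-9)
        phi = solve_scdem(moving, tissue48, None, p)
        assert np.all(np.isfinite(phi.vectors))


class TestRegisterPair:
    def test_self_registration_near_identity(self):
        scan = make_phantom(12.0, GrowthModel(noise_sd=0.0), default_grid(32, 3.0),
                            seed=6, mesh_subdivisions=2)
        params = ScdemParams(alpha=0.15, beta=8.0, gamma=0.0, max_steps=60,
                             force_tol=1e-6)
        aff, phi = register_pair(scan, scan, params, use_surfaces=False)
        assert np.abs(aff.matrix - np.eye(3)).max() < 1e-6
        assert np.abs(phi.vectors).max() / 3.0 < 0.05  # voxels

    def test_registration_improves_wm_dice_over_affine(self):
        grid = default_grid(48, 2.0)
        g = GrowthModel(noise_sd=0.0)
        fixed = make_phantom(12.0, g, grid, seed=21)
        moving = make_phantom(12.0, g, grid, seed=22)
        params = ScdemParams(alpha=0.15, beta=8.0, gamma=0.0, max_steps=150,
                             force_tol=1e-6)
        aff, phi = register_pair(moving, fixed, params, use_surfaces=False)
        moved = apply_affine_to_tissue_map(moving.tissue, aff, grid)
        warped = warp_tissue_map(moved, phi)

        def dice(a, b):
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        fix_wm = fixed.tissue.channel("WM") > 0.5
        d_affine = dice(moved.channel("WM") > 0.5, fix_wm)
        d_full = dice(warped.channel("WM") > 0.5, fix_wm)
        assert d_full > d_affine
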