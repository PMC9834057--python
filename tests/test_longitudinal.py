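"""Parallel transport, kernel regression of fields, atlas propagation."""

import numpy as np
import pytest

from svatlas.atlas import TemporalKernel
from svatlas.data_model import (
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    TissueProbMap,
    sample_vectors,
)
from svatlas.longitudinal import (
    CoverageError,
    LongitudinalPair,
    build_all_months,
    build_month_intensity_atlas,
    kernel_regress_fields,
    parallel_transport,
    propagate_atlas,
)
from svatlas.subjects import AtlasBundle, HemiSurfaces, SubjectScan
from svatlas.surface import TriangleMesh
from svatlas.synth import default_grid, make_icosphere, make_known_deformation


def small_field(grid, seed, max_mm=1.5):
    return make_known_deformation(grid, max_mm, 10.0, seed=seed)


class TestParallelTransport:
    def test_identity_atlas_transform_returns_longitudinal_field(self, small_grid):
        phi_l = small_field(small_grid, 1)
        pair = LongitudinalPair("s", 6.0, 12.0, phi_l, DisplacementField.zeros(small_grid))
        out = parallel_transport(pair)
        assert np.abs(out.vectors - phi_l.vectors).max() < 1e-12

    def test_identity_longitudinal_gives_near_zero(self, small_grid):
        phi_a = small_field(small_grid, 2)
        pair = LongitudinalPair("s", 6.0, 12.0, DisplacementField.zeros(small_grid), phi_a)
        out = parallel_transport(pair, tol=1e-4)
        interior = (slice(2, -2),) * 3
        assert np.abs(out.vectors[interior]).max() / 2.0 < 0.05  # voxels

    def test_matches_pointwise_chain_oracle(self):
        from svatlas.experiments import exp_transport_oracle

        out = exp_transport_oracle()
        assert out["transport_chain_max_err_vox"] < 0.05
        assert out["transport_identity_conjugation_err_mm"] == 0.0

    def test_small_deformation_linearity(self, small_grid):
        # as |phi_long| -> 0 the transported field approaches phi_long
        phi_a = small_field(small_grid, 3)
        tiny = DisplacementField(small_grid, 0.05 * small_field(small_grid, 4).vectors)
        pair = LongitudinalPair("s", 6.0, 12.0, tiny, phi_a)
        out = parallel_transport(pair, tol=1e-4)
        interior = (slice(2, -2),) * 3
        # 0.1-voxel scale agreement
        assert np.abs(out.vectors[interior] - tiny.vectors[interior]).max() / 2.0 < 0.1


class TestKernelRegression:
    def test_single_pair_returned_exactly(self, small_grid):
        f = small_field(small_grid, 5)
        pair = LongitudinalPair(
            "s", 5.5, 12.0, f, DisplacementField.zeros(small_grid), transported=f
        )
        out = kernel_regress_fields([pair], tau0=5.0)
        assert np.array_equal(out.vectors, f.vectors)

    def test_equal_age_pairs_plain_mean(self, small_grid):
        f1, f2 = small_field(small_grid, 6), small_field(small_grid, 7)
        mk = lambda f: LongitudinalPair(
            "s", 5.5, 12.0, f, DisplacementField.zeros(small_grid), transported=f
        )
        out = kernel_regress_fields([mk(f1), mk(f2)], tau0=5.0)
        assert np.allclose(out.vectors, 0.5 * (f1.vectors + f2.vectors), atol=1e-12)

    def test_matches_literal_formula(self, small_grid):
        kern = TemporalKernel()
        ages = [(4.5, 11.0), (5.5, 12.0), (6.0, 13.0)]
        pairs, fields = [], []
        for i, (tp, t) in enumerate(ages):
            f = small_field(small_grid, 10 + i)
            fields.append(f)
            pairs.append(LongitudinalPair(
                f"s{i}", tp, t, f, DisplacementField.zeros(small_grid), transported=f))
        out = kernel_regress_fields(pairs, tau0=5.0, kernel=kern)
        w = np.array([kern.weight(tp, 5.0) * kern.weight(t, 12.0) for tp, t in ages])
        w /= w.sum()
        manual = sum(wi * f.vectors for wi, f in zip(w, fields))
        assert np.abs(out.vectors - manual).max() < 1e-12
        assert abs(w.sum() - 1.0) < 1e-12

    def test_out_of_window_pairs_excluded(self, small_grid):
        f = small_field(small_grid, 20)
        inside = LongitudinalPair(
            "a", 5.5, 12.0, f, DisplacementField.zeros(small_grid), transported=f
        )
        far = LongitudinalPair(
            "b", 20.0, 12.0, small_field(small_grid, 21),
            DisplacementField.zeros(small_grid),
            transported=small_field(small_grid, 21),
        )
        out = kernel_regress_fields([inside, far], tau0=5.0)
        assert np.array_equal(out.vectors, f.vectors)

    def test_no_coverage_raises(self, small_grid):
        f = small_field(small_grid, 22)
        pair = LongitudinalPair(
            "a", 20.0, 12.0, f, DisplacementField.zeros(small_grid), transported=f
        )
        with pytest.raises(CoverageError):
            kernel_regress_fields([pair], tau0=5.0)


def toy_bundle(grid):
    rng = np.random.default_rng(3)
    from scipy.ndimage import gaussian_filter

    x = grid.world_coords()
    r = np.linalg.norm(x, axis=-1)
    wm = gaussian_filter((r < 10).astype(float), 0.8)
    gm = gaussian_filter(((r >= 10) & (r < 14)).astype(float), 0.8)
    chans = np.clip(np.stack([wm, gm, np.zeros_like(wm)], -1), 0, 1)
    ico = make_icosphere(2, 10.0)
    hemi = HemiSurfaces(
        TriangleMesh(ico.vertices.copy(), ico.triangles.copy()),
        TriangleMesh(ico.vertices * 1.4, ico.triangles.copy()),
    )
    lab = np.zeros(grid.shape, dtype=np.int16)
    lab[r < 10] = 3
    lab[(r >= 10) & (r < 14)] = 2
    return AtlasBundle(
        age_months=12.0,
        t1w=ScalarVolume(grid, gaussian_filter(rng.normal(size=grid.shape), 2.0)),
        t2w=ScalarVolume(grid, gaussian_filter(rng.normal(size=grid.shape), 2.0)),
        tissue_prob=TissueProbMap(grid, chans),
        tissue_label=LabelVolume(grid, lab),
        surfaces={"lh": hemi},
    )


class TestPropagation:
    def test_identity_field_leaves_bundle_unchanged(self):
        grid = default_grid(32, 2.0)
        bundle = toy_bundle(grid)
        out = propagate_atlas(bundle, DisplacementField.zeros(grid), age_months=6.0)
        assert np.array_equal(out.tissue_prob.channels, bundle.tissue_prob.channels)
        assert np.array_equal(out.surfaces["lh"].white.vertices,
                              bundle.surfaces["lh"].white.vertices)
        assert out.age_months == 6.0

    def test_translation_moves_volumes_and_surfaces_consistently(self):
        grid = default_grid(32, 2.0)
        bundle = toy_bundle(grid)
        t = np.array([2.0, 0.0, 0.0])
        f = DisplacementField(grid, np.broadcast_to(t, grid.shape + (3,)).copy())
        out = propagate_atlas(bundle, f)
        # volumes: out(x) = in(x + t) -> content appears at x_feature - t
        assert np.allclose(
            out.tissue_prob.channels[:-1], bundle.tissue_prob.channels[1:], atol=1e-9
        )
        # surfaces move by the inverse (-t), matching the volume shift
        assert np.allclose(
            out.surfaces["lh"].white.vertices,
            bundle.surfaces["lh"].white.vertices - t,
            atol=1e-3,
        )

    def test_uniform_scaling_changes_wm_volume_by_jacobian(self):
        grid = default_grid(32, 2.0)
        bundle = toy_bundle(grid)
        s = 1.1  # pull-back scaling: out(x) = in(s x) shrinks content by s^3
        x = grid.world_coords()
        f = DisplacementField(grid, (s - 1.0) * x)
        out = propagate_atlas(bundle, f)
        v_in = bundle.tissue_prob.channel("WM").sum()
        v_out = out.tissue_prob.channel("WM").sum()
        assert v_out / v_in == pytest.approx(1.0 / s**3, rel=0.02)


class TestMonthIntensity:
    def test_identity_transforms_return_own_image(self):
        grid = default_grid(24, 3.0)
        bundle = toy_bundle(grid)
        z = DisplacementField.zeros(grid)
        scan = SubjectScan("s", 5.5, bundle.t1w, bundle.t2w, bundle.tissue_prob)
        pair = LongitudinalPair("s", 5.5, 12.0, z, z, transported=z, scan_prime=scan)
        t1, t2 = build_month_intensity_atlas([pair], 5.0, z)
        assert np.allclose(t1.values, bundle.t1w.values, atol=1e-12)

    def test_two_identical_images_average_to_same(self):
        grid = default_grid(24, 3.0)
        bundle = toy_bundle(grid)
        z = DisplacementField.zeros(grid)
        scan = SubjectScan("s", 5.5, bundle.t1w, bundle.t2w, bundle.tissue_prob)
        mk = lambda sid, tp: LongitudinalPair(
            sid, tp, 12.0, z, z, transported=z, scan_prime=scan
        )
        t1, _ = build_month_intensity_atlas([mk("a", 5.0), mk("b", 6.0)], 5.5, z)
        assert np.allclose(t1.values, bundle.t1w.values, atol=1e-12)


class TestBuildAllMonths:
    def test_uncovered_months_skipped_with_report(self):
        grid = default_grid(16, 4.0)
        bundle = toy_bundle(grid)
        z = DisplacementField.zeros(grid)
        pair = LongitudinalPair("s", 5.5, 12.0, z, z, transported=z)
        res = build_all_months([pair], bundle, [5.0, 20.0], with_intensity=False)
        assert 5.0 in res.months and 20.0 in res.skipped
        assert res.coverage[5.0] == 1
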