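"""Atlas construction: temporal weighting, reference selection, fusion,
corrective displacement, surface atlas."""

import numpy as np
import pytest

from svatlas.atlas import (
    AgeWindow,
    TemporalKernel,
    build_surface_atlas,
    corrective_displacement,
    fuse_intensity,
    fuse_labels_majority,
    select_reference,
    temporal_weight,
    total_pullback_field,
)
from svatlas.data_model import (
    AffineTransform,
    DisplacementField,
    ScalarVolume,
    TissueProbMap,
    ValidationError,
    apply_affine_to_volume,
    warp_scalar_volume,
    warp_tissue_map,
)
from svatlas.subjects import HemiSurfaces
from svatlas.surface import TriangleMesh
from svatlas.synth import GrowthModel, default_grid, make_icosphere, make_phantom


class TestTemporalKernel:
    def test_peak_value(self):
        k = TemporalKernel(0.7)
        assert k.weight(12, 12) == pytest.approx(1.0 / (0.7 * np.sqrt(2 * np.pi)))

    def test_symmetry(self, rng):
        k = TemporalKernel(0.7)
        for _ in range(5):
            a, b = rng.uniform(0, 24, 2)
            assert k.weight(a, b) == pytest.approx(k.weight(b, a))

    def test_printed_formula_ratio(self):
        k = TemporalKernel(0.7)
        assert k.weight(11, 12) / k.weight(12, 12) == pytest.approx(
            np.exp(-1.0 / (2 * 0.49))
        )

    def test_window_membership_closed(self):
        w = AgeWindow(12.0, 1.5)
        assert w.contains(10.5) and w.contains(13.5)
        assert not w.contains(10.49) and not w.contains(13.51)


class TestSelectReference:
    def make_scan(self, sid, tissue):
        from svatlas.subjects import SubjectScan

        grid = tissue.grid
        z = ScalarVolume(grid, np.zeros(grid.shape))
        return SubjectScan(sid, 12.0, z, z, tissue)

    def test_single_scan(self, small_grid, rng):
        t = TissueProbMap(small_grid, np.clip(rng.uniform(0, 0.3, small_grid.shape + (3,)), 0, 1))
        s = self.make_scan("a", t)
        assert select_reference([s]) is s

    def test_identical_maps_tie_break_by_id(self, small_grid, rng):
        chans = np.clip(rng.uniform(0, 0.3, small_grid.shape + (3,)), 0, 1)
        scans = [
            self.make_scan(sid, TissueProbMap(small_grid, chans.copy()))
            for sid in ("b", "a", "c")
        ]
        assert select_reference(scans).subject_id == "a"

    def test_outlier_never_selected(self):
        grid = default_grid(32, 3.0)
        g = GrowthModel(noise_sd=0.0)
        scans = []
        for i in range(5):
            s = make_phantom(12.0, g, grid, seed=30 + i, subject_id=f"s{i}",
                             mesh_subdivisions=2)
            scans.append(s)
        # make one an outlier: heavily dilated WM
        from scipy.ndimage import grey_dilation

        out = scans[2]
        ch = out.tissue.channels.copy()
        ch[..., 0] = grey_dilation(ch[..., 0], size=(5, 5, 5))
        s = ch.sum(-1, keepdims=True)
        np.divide(ch, s, out=ch, where=s > 1)
        out.tissue = TissueProbMap(grid, np.clip(ch, 0, 1))
        assert select_reference(scans).subject_id != "s2"


class TestFusion:
    def test_identical_maps_fuse_to_own_argmax(self, small_grid, rng):
        chans = np.clip(rng.uniform(0, 0.4, small_grid.shape + (3,)), 0, 1)
        s = chans.sum(-1, keepdims=True)
        np.divide(chans, s, out=chans, where=s > 1)
        m = TissueProbMap(small_grid, chans)
        fused = fuse_labels_majority([m, m, m], [1, 1, 1])
        stack = np.concatenate([m.channels, m.background[..., None]], axis=-1)
        cls = np.argmax(stack, axis=-1)
        code = np.array([3, 2, 1, 0])
        assert np.array_equal(fused.labels, code[cls])

    def test_tie_breaks_prefer_wm(self, small_grid):
        gm_map = np.zeros(small_grid.shape + (3,))
        gm_map[..., 1] = 0.9
        wm_map = np.zeros(small_grid.shape + (3,))
        wm_map[..., 0] = 0.9
        fused = fuse_labels_majority(
            [TissueProbMap(small_grid, gm_map), TissueProbMap(small_grid, wm_map)],
            [1.0, 1.0],
        )
        assert np.all(fused.labels == 3)

    def test_matches_bruteforce_tally(self, small_grid, rng):
        maps, weights = [], []
        for i in range(5):
            ch = np.clip(rng.uniform(0, 0.4, small_grid.shape + (3,)), 0, 1)
            s = ch.sum(-1, keepdims=True)
            np.divide(ch, s, out=ch, where=s > 1)
            maps.append(TissueProbMap(small_grid, ch))
            weights.append(float(rng.uniform(0.1, 2.0)))
        fused = fuse_labels_majority(maps, weights)
        # brute force per voxel
        code = np.array([3, 2, 1, 0])
        votes = np.zeros(small_grid.shape + (4,))
        for m, w in zip(maps, weights):
            stack = np.concatenate([m.channels, m.background[..., None]], axis=-1)
            cls = np.argmax(stack, axis=-1)
            for c in range(4):
                votes[..., c] += w * (cls == c)
        assert np.array_equal(fused.labels, code[np.argmax(votes, axis=-1)])

    def test_zero_weights_rejected(self, small_grid):
        m = TissueProbMap(small_grid, np.zeros(small_grid.shape + (3,)))
        with pytest.raises(ValidationError):
            fuse_labels_majority([m], [0.0])

    def test_intensity_weighted_mean(self, small_grid, rng):
        imgs = [ScalarVolume(small_grid, rng.normal(size=small_grid.shape)) for _ in range(3)]
        w = [0.2, 0.5, 1.3]
        fused = fuse_intensity(imgs, w)
        expected = sum(wi * im.values for wi, im in zip(w, imgs)) / sum(w)
        assert np.allclose(fused.values, expected, atol=1e-12)
        assert fused.values.min() >= min(i.values.min() for i in imgs)
        assert fused.values.max() <= max(i.values.max() for i in imgs)

    def test_single_image_identity(self, small_grid, rng):
        img = ScalarVolume(small_grid, rng.normal(size=small_grid.shape))
        assert np.array_equal(fuse_intensity([img], [2.0]).values, img.values)


class TestSurfaceAtlas:
    def hemi(self, scale=1.0, offset=0.0):
        ico = make_icosphere(2, 20.0 * scale)
        w = TriangleMesh(ico.vertices + offset, ico.triangles.copy())
        p = TriangleMesh(ico.vertices * 1.1 + offset, ico.triangles.copy())
        return {"lh": HemiSurfaces(w, p)}

    def test_single_subject_returns_itself(self):
        s = self.hemi()
        out = build_surface_atlas([s], [11.0], TemporalKernel(), 12.0)
        assert np.array_equal(out["lh"].white.vertices, s["lh"].white.vertices)

    def test_equal_ages_unweighted_mean(self):
        a, b = self.hemi(1.0), self.hemi(1.2)
        out = build_surface_atlas([a, b], [12.0, 12.0], TemporalKernel(), 12.0)
        expected = 0.5 * (a["lh"].white.vertices + b["lh"].white.vertices)
        assert np.allclose(out["lh"].white.vertices, expected, atol=1e-12)

    def test_symmetric_ages_give_5050(self):
        a, b = self.hemi(1.0), self.hemi(1.3)
        out = build_surface_atlas([a, b], [11.0, 13.0], TemporalKernel(), 12.0)
        expected = 0.5 * (a["lh"].white.vertices + b["lh"].white.vertices)
        assert np.allclose(out["lh"].white.vertices, expected, atol=1e-12)

    def test_indexing_mismatch_rejected(self):
        a = self.hemi()
        ico = make_icosphere(1, 20.0)
        b = {"lh": HemiSurfaces(TriangleMesh(ico.vertices, ico.triangles),
                                TriangleMesh(ico.vertices * 1.1, ico.triangles))}
        with pytest.raises(ValidationError):
            build_surface_atlas([a, b], [12.0, 12.0], TemporalKernel(), 12.0)


class TestCorrectiveDisplacement:
    def make_surfaces(self, radius=10.0):
        ico = make_icosphere(2, radius)
        white = TriangleMesh(ico.vertices.copy(), ico.triangles.copy())
        pial = TriangleMesh(ico.vertices * 1.05, ico.triangles.copy())
        return {"lh": HemiSurfaces(white, pial)}

    def test_constant_displacement_reproduced_near_surface(self, rng):
        grid = default_grid(16, 2.0)
        surfs = self.make_surfaces()
        v = np.array([1.0, -2.0, 0.5])
        n = surfs["lh"].white.n_vertices()
        disp = {("lh", "white"): np.tile(v, (n, 1)), ("lh", "pial"): np.tile(v, (n, 1))}
        out = corrective_displacement(surfs, disp, grid)
        x = grid.world_coords()
        r = np.linalg.norm(x, axis=-1)
        near = np.abs(r - 10.0) < 1.0  # well within delta of the white surface
        vals = out.vectors[near]
        assert np.allclose(vals, v, atol=1e-9)

    def test_far_voxels_exactly_zero(self):
        grid = default_grid(24, 2.0)
        surfs = self.make_surfaces(radius=8.0)
        n = surfs["lh"].white.n_vertices()
        disp = {("lh", "white"): np.ones((n, 3)), ("lh", "pial"): np.ones((n, 3))}
        out = corrective_displacement(surfs, disp, grid, delta=6.0)
        x = grid.world_coords().reshape(-1, 3)
        from scipy.spatial import cKDTree

        all_verts = np.vstack([surfs["lh"].white.vertices, surfs["lh"].pial.vertices])
        d = cKDTree(all_verts).query(x)[0].reshape(grid.shape)
        assert np.all(out.vectors[d > 6.0] == 0)

    def test_matches_exhaustive_oracle(self):
        from svatlas.experiments import exp_corrective_oracle

        out = exp_corrective_oracle()
        assert out["corrective_oracle_max_diff_mm"] <= 1e-10
        assert out["corrective_far_voxel_max_mm"] == 0.0


class TestTotalField:
    def test_affine_then_field_equals_combined(self, small_grid, rng):
        from scipy.ndimage import gaussian_filter

        # smooth image: the comparison isolates the map algebra from
        # double-interpolation noise
        img = ScalarVolume(small_grid, gaussian_filter(rng.normal(size=small_grid.shape), 2.0))
        aff = AffineTransform(np.diag([1.05, 1.0, 0.95]), np.array([1.0, -1.0, 0.0]))
        from conftest import smooth_field

        phi = smooth_field(small_grid, 1.0, seed=11)
        total = total_pullback_field(aff, phi)
        via_total = warp_scalar_volume(img, total)
        moved = apply_affine_to_volume(img, aff, small_grid)
        via_steps = warp_scalar_volume(moved, phi)
        interior = (slice(2, -2),) * 3
        # single-interpolation total vs two-step resampling agree to
        # interpolation error
        assert (
            np.abs(via_total.values[interior] - via_steps.values[interior]).mean() < 0.05
        )
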