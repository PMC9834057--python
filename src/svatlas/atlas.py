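"""Reference (12-month) surface-volume atlas construction.

Pipeline: select the reference scan most similar to the whole cohort,
groupwise SC-DEM registration with an iteratively fused reference map,
temporally weighted surface atlas, surface-corrected volumetric fusion
(corrective displacement with Gaussian vertex weights, delta = 6 mm,
sigma_g = 3 mm), majority-vote tissue labels and weighted intensity
averaging.  The temporal kernel w(tau1, tau2) is Gaussian with
sigma = 0.7 months; the reference age window is +-1.5 months around the
window centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .data_model import (
    AffineTransform,
    DisplacementField,
    LabelVolume,
    ScalarVolume,
    TissueProbMap,
    ValidationError,
    VoxelGrid,
    compose_displacements,
    invert_displacement,
    sample_vectors,
    warp_scalar_volume,
    warp_tissue_map,
)
from .scdem import ScdemParams, affine_align, solve_scdem, spherical_map_of
from .sphere_reg import propagate_to_anatomical, register_spherical_maps
from .subjects import AtlasBundle, HemiSurfaces, SubjectScan
from .surface import SphericalMap, TriangleMesh, resample_attribute_on_sphere
from .data_model import apply_affine_to_tissue_map

__all__ = [
    "TemporalKernel",
    "AgeWindow",
    "temporal_weight",
    "select_reference",
    "groupwise_register",
    "build_surface_atlas",
    "corrective_displacement",
    "fuse_labels_majority",
    "fuse_intensity",
    "fuse_tissue_probability",
    "total_pullback_field",
    "build_reference_atlas",
    "ReferenceAtlasResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalKernel:
    """Gaussian age-weighting kernel; sigma in months."""

    sigma: float = 0.7

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("kernel sigma must be > 0")

    def weight(self, tau1: float, tau2: float) -> float:
        s = self.sigma
        return float(
            np.exp(-((tau1 - tau2) ** 2) / (2.0 * s**2)) / (s * np.sqrt(2.0 * np.pi))
        )


def temporal_weight(kernel: TemporalKernel, tau1: float, tau2: float) -> float:
    return kernel.weight(tau1, tau2)


@dataclass(frozen=True)
class AgeWindow:
    """Closed age interval [center - half_width, center + half_width] months."""

    center: float
    half_width: float = 1.5

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValidationError("window half-width must be > 0")

    def contains(self, age: float) -> bool:
        return self.center - self.half_width <= age <= self.center + self.half_width

    def filter(self, scans: list[SubjectScan]) -> list[SubjectScan]:
        return [s for s in scans if self.contains(s.age_months)]


# --------------------------------------------------------------------------
# reference selection
# --------------------------------------------------------------------------


def _centroid(tmap: TissueProbMap) -> np.ndarray:
    w = tmap.channels.sum(axis=-1)
    total = w.sum()
    if total <= 0:
        raise ValidationError("empty tissue map")
    x = tmap.grid.world_coords()
    return (w[..., None] * x).reshape(-1, 3).sum(axis=0) / total


def select_reference(scans: list[SubjectScan]) -> SubjectScan:
    """The scan whose tissue map is most similar (mean SSD) to all others.

    Maps are rigidly aligned by centroid translation before comparison.
    Deterministic tie-break: smallest (subject id, age).
    """
    if not scans:
        raise ValidationError("empty cohort window")
    if len(scans) == 1:
        return scans[0]
    cents = [_centroid(s.tissue) for s in scans]
    mean_cent = np.mean(cents, axis=0)
    aligned = []
    for s, c in zip(scans, cents):
        shift = c - mean_cent  # pull-back field: sample at x + (c - mean)
        f = DisplacementField(
            s.tissue.grid,
            np.broadcast_to(shift, s.tissue.grid.shape + (3,)).copy(),
        )
        aligned.append(warp_tissue_map(s.tissue, f).channels)
    n = len(scans)
    cost = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                cost[i] += float(((aligned[i] - aligned[j]) ** 2).mean())
    cost /= n - 1
    order = sorted(
        range(n), key=lambda i: (cost[i], scans[i].subject_id, scans[i].age_months)
    )
    return scans[order[0]]


# --------------------------------------------------------------------------
# groupwise registration
# --------------------------------------------------------------------------


@dataclass
class _PerScanReg:
    affine: AffineTransform
    phi: DisplacementField
    warp_by_hemi: dict  # hemi -> (SphericalWarp, fixed SphericalMap)
    moved_tissue: TissueProbMap  # affine-resampled moving map
    constraints: list


def _surface_constraints_for(
    moving: SubjectScan,
    reference: SubjectScan,
    affine: AffineTransform,
    ref_spheres: dict[str, SphericalMap],
    sphere_opts: dict | None = None,
    injected_warps: dict | None = None,
):
    """Spherical registration to the reference subject -> SC-DEM constraints.

    Returns (constraints, warps) where constraints anchor the residual at the
    corresponding reference-surface points with displacement pointing back to
    the (affine-aligned) moving surface.  `injected_warps` (hemi ->
    SphericalWarp) bypasses the internal registration, e.g. with
    correspondences from an external tool.
    """
    from .scdem import SurfaceConstraint

    constraints, warps = [], {}
    for hemi in sorted(set(moving.surfaces) & set(reference.surfaces)):
        mov_h, fix_h = moving.surfaces[hemi], reference.surfaces[hemi]
        mov_white = TriangleMesh(affine.apply(mov_h.white.vertices), mov_h.white.triangles)
        mov_pial = TriangleMesh(affine.apply(mov_h.pial.vertices), mov_h.pial.triangles)
        fix_sphere = ref_spheres[hemi]
        if injected_warps and hemi in injected_warps:
            warp = injected_warps[hemi]
        else:
            mov_sphere = spherical_map_of(mov_white)
            warp = register_spherical_maps(mov_sphere, fix_sphere, **(sphere_opts or {}))
        dw, dp = propagate_to_anatomical(
            warp, mov_white, mov_pial, fix_h.white, fix_h.pial, fix_sphere
        )
        for mesh, d in ((mov_white, dw), (mov_pial, dp)):
            constraints.append(
                SurfaceConstraint(points=mesh.vertices + d, target_disp=-d)
            )
        warps[hemi] = (warp, fix_sphere, (mov_white, mov_pial))
    return constraints, warps


def groupwise_register(
    scans: list[SubjectScan],
    params: ScdemParams | None = None,
    n_rounds: int = 2,
    reference: SubjectScan | None = None,
    use_surfaces: bool = True,
    sphere_opts: dict | None = None,
    correspondences: dict | None = None,
) -> tuple[dict, TissueProbMap, SubjectScan]:
    """Groupwise SC-DEM registration with iterative reference fusion.

    Round 0 registers every scan to the selected reference subject's tissue
    map; each later round replaces the reference map by the unweighted mean
    of the warped maps and re-registers.  Surface constraints (against the
    reference subject's surfaces) are computed once and reused.  Returns
    ({scan key: _PerScanReg}, final reference map, reference scan).
    """
    if not scans:
        raise ValidationError("empty cohort")
    params = params or ScdemParams()
    reference = reference or select_reference(scans)
    ref_map = reference.tissue
    grid = ref_map.grid

    ref_spheres = {}
    if use_surfaces and params.gamma > 0 and reference.surfaces:
        for hemi in reference.surfaces:
            ref_spheres[hemi] = spherical_map_of(reference.surfaces[hemi].white)

    regs: dict = {}
    for s in scans:
        aff = (
            AffineTransform.identity()
            if s.key == reference.key
            else affine_align(s.tissue, ref_map)
        )
        moved = apply_affine_to_tissue_map(s.tissue, aff, grid)
        constraints = []
        warps = {}
        if ref_spheres and s.surfaces:
            constraints, warps = _surface_constraints_for(
                s, reference, aff, ref_spheres,
                sphere_opts=sphere_opts,
                injected_warps=(correspondences or {}).get(s.key),
            )
        regs[s.key] = _PerScanReg(aff, DisplacementField.zeros(grid), warps, moved, constraints)

    current_ref = ref_map
    dice_track = []
    for rnd in range(n_rounds + 1):
        warped_maps = []
        for s in scans:
            r = regs[s.key]
            phi = solve_scdem(r.moved_tissue, current_ref, r.constraints, params)
            r.phi = phi
            warped_maps.append(warp_tissue_map(r.moved_tissue, phi))
        dice = _mean_wm_dice(warped_maps, current_ref)
        dice_track.append(dice)
        if len(dice_track) > 1 and dice < dice_track[-2] - 1e-6:
            log.warning(
                "groupwise round %d decreased mean WM Dice: %.4f -> %.4f",
                rnd, dice_track[-2], dice,
            )
        if rnd == n_rounds:
            break
        mean_chans = np.mean([m.channels for m in warped_maps], axis=0)
        fused = TissueProbMap(grid, np.clip(mean_chans, 0.0, 1.0))
        if any(regs[s.key].constraints for s in scans):
            # surface constraints target the reference subject's surfaces;
            # moving the volumetric reference away from them would make the
            # two forces fight, so the reference stays anchored here
            current_ref = fused
            continue
        # de-bias: recentre the reference at the population barycenter by
        # resampling the fused map with the inverse of the mean *total*
        # (affine + nonlinear) map — otherwise the groupwise atlas stays
        # anchored at the initial reference subject's shape.  The affine part
        # is inverted analytically (it grows linearly at the grid corners,
        # where fixed-point inversion cannot converge); the nonlinear mean is
        # inverted by fixed point.
        from .data_model import affine_to_displacement

        mean_aff = AffineTransform(
            np.mean([regs[s.key].affine.matrix for s in scans], axis=0),
            np.mean([regs[s.key].affine.translation for s in scans], axis=0),
        )
        mu_phi = DisplacementField(
            grid, np.mean([regs[s.key].phi.vectors for s in scans], axis=0)
        )
        try:
            inv_phi = invert_displacement(mu_phi, max_iter=60, tol=1e-2)
        except Exception as exc:
            # local folds in the mean field: a pseudo-inverse still
            # recentres the smooth bulk, which is all de-biasing needs
            log.info("de-biasing with pseudo-inverse (%s)", exc)
            from .data_model import invert_displacement_best_effort

            inv_phi = invert_displacement_best_effort(mu_phi)
        # point map y -> Phi_mu^{-1}(mean_aff(y))
        recentre = compose_displacements(
            inv_phi, affine_to_displacement(mean_aff.inverse(), grid)
        )
        current_ref = warp_tissue_map(fused, recentre)
    log.info("groupwise Dice per round: %s", [f"{d:.4f}" for d in dice_track])
    return regs, current_ref, reference


def _mean_wm_dice(maps: list[TissueProbMap], ref: TissueProbMap) -> float:
    ref_wm = ref.channel("WM") > 0.5
    out = []
    for m in maps:
        wm = m.channel("WM") > 0.5
        denom = wm.sum() + ref_wm.sum()
        out.append(2.0 * (wm & ref_wm).sum() / denom if denom else 1.0)
    return float(np.mean(out))


# --------------------------------------------------------------------------
# surface atlas
# --------------------------------------------------------------------------


def build_surface_atlas(
    registered_surfaces: list[dict[str, HemiSurfaces]],
    ages: list[float],
    kernel: TemporalKernel,
    center: float,
) -> dict[str, HemiSurfaces]:
    """Temporally weighted average of vertex coordinates on shared indexing."""
    if len(registered_surfaces) != len(ages):
        raise ValidationError("surfaces/ages length mismatch")
    if not registered_surfaces:
        raise ValidationError("no surfaces to average")
    w = np.array([kernel.weight(a, center) for a in ages])
    w = w / w.sum()
    out: dict[str, HemiSurfaces] = {}
    for hemi in registered_surfaces[0]:
        n_v = len(registered_surfaces[0][hemi].white.vertices)
        tris = registered_surfaces[0][hemi].white.triangles
        acc = {"white": np.zeros((n_v, 3)), "pial": np.zeros((n_v, 3))}
        for wi, surfs in zip(w, registered_surfaces):
            hs = surfs[hemi]
            for name, mesh in (("white", hs.white), ("pial", hs.pial)):
                if len(mesh.vertices) != n_v:
                    raise ValidationError("shared indexing violated in surface atlas")
                acc[name] += wi * mesh.vertices
        out[hemi] = HemiSurfaces(
            TriangleMesh(acc["white"], tris.copy()), TriangleMesh(acc["pial"], tris.copy())
        )
    return out


# --------------------------------------------------------------------------
# Eq.-3 style corrective displacement
# --------------------------------------------------------------------------


def _point_triangle_distance(p: np.ndarray, a, b, c):
    """Vectorized point-to-triangle squared distance (per row)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    # barycentric regions (Ericson, Real-Time Collision Detection)
    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    closest[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    wv = d2 / np.where(d2 - d6 == 0, 1, d2 - d6)
    closest[m] = a[m] + wv[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    wv = (d4 - d3) / np.where(denom == 0, 1, denom)
    closest[m] = b[m] + wv[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    wv = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + wv[m, None] * ac[m]

    d = ((p - closest) ** 2).sum(-1)
    return d, closest


def _pool_surfaces(
    surfaces: dict[str, HemiSurfaces], disp: dict[tuple[str, str], np.ndarray] | None
):
    """Concatenate white+pial of both hemispheres into one vertex/triangle set."""
    verts, tris, dvals = [], [], []
    offset = 0
    for hemi in sorted(surfaces):
        hs = surfaces[hemi]
        for name, mesh in (("white", hs.white), ("pial", hs.pial)):
            verts.append(mesh.vertices)
            tris.append(mesh.triangles + offset)
            if disp is not None:
                d = np.asarray(disp[(hemi, name)], dtype=float)
                if d.shape != mesh.vertices.shape:
                    raise ValidationError(
                        f"displacement shape mismatch for {hemi} {name}"
                    )
                dvals.append(d)
            offset += len(mesh.vertices)
    v = np.vstack(verts)
    t = np.vstack(tris)
    d = np.vstack(dvals) if disp is not None else None
    return v, t, d


def corrective_displacement(
    atlas_surfaces: dict[str, HemiSurfaces],
    surface_disp: dict[tuple[str, str], np.ndarray],
    grid: VoxelGrid,
    sigma_g: float = 3.0,
    delta: float = 6.0,
    k_candidates: int = 16,
) -> DisplacementField:
    """Corrective volumetric displacement from vertex-wise surface residuals.

    For each voxel, the closest triangle (point-to-triangle distance over the
    pooled white+pial surfaces of both hemispheres) is found; if the voxel is
    within `delta` of *all three* of its vertices, the corrective value is
    the Gaussian-weighted (width sigma_g) mean of the three vertex
    displacements, else exactly zero.
    """
    verts, tris, dvals = _pool_surfaces(atlas_surfaces, surface_disp)
    areas = np.linalg.norm(
        np.cross(verts[tris[:, 1]] - verts[tris[:, 0]], verts[tris[:, 2]] - verts[tris[:, 0]]),
        axis=1,
    )
    good = areas > 1e-12
    if not good.all():
        log.warning("skipping %d degenerate triangles", int((~good).sum()))
        tris = tris[good]

    x = grid.world_coords().reshape(-1, 3)
    # candidate pruning: voxels farther than delta + max circumradius from
    # every triangle centroid cannot pass the delta test
    centroids = verts[tris].mean(axis=1)
    tree = cKDTree(centroids)
    tri_rad = np.linalg.norm(verts[tris] - centroids[:, None, :], axis=-1).max()
    near = tree.query_ball_point(x, r=delta + tri_rad, return_length=True) > 0
    out = np.zeros((len(x), 3))
    idx = np.flatnonzero(near)
    if idx.size:
        n_tris = len(tris)

        def scan_candidates(points, cand, best_d, best_tri):
            # lexicographic tie-break (distance, triangle index): matches
            # the exhaustive oracle bitwise
            for col in range(cand.shape[1]):
                tid = cand[:, col]
                d2, _ = _point_triangle_distance(
                    points, verts[tris[tid, 0]], verts[tris[tid, 1]], verts[tris[tid, 2]]
                )
                upd = (d2 < best_d - 1e-12) | (
                    (np.abs(d2 - best_d) <= 1e-12) & (tid < best_tri)
                )
                best_d[upd] = d2[upd]
                best_tri[upd] = tid[upd]

        pts = x[idx]
        best_d = np.full(len(idx), np.inf)
        best_tri = np.zeros(len(idx), dtype=int)
        # adaptive candidate search: the true closest triangle's centroid
        # lies within sqrt(best_d) + tri_rad, so grow k until the k-th
        # candidate centroid is provably beyond that bound
        active = np.arange(len(idx))
        k = min(k_candidates, n_tris)
        while active.size:
            ckd, cand = tree.query(pts[active], k=k)
            if cand.ndim == 1:
                ckd, cand = ckd[:, None], cand[:, None]
            sub_d = best_d[active]
            sub_t = best_tri[active]
            scan_candidates(pts[active], cand, sub_d, sub_t)
            best_d[active] = sub_d
            best_tri[active] = sub_t
            if k >= n_tris:
                break
            unsure = ckd[:, -1] <= np.sqrt(sub_d) + tri_rad + 1e-9
            active = active[unsure]
            k = min(4 * k, n_tris)
        corner = verts[tris[best_tri]]  # (n, 3, 3)
        dist_v = np.linalg.norm(corner - x[idx][:, None, :], axis=-1)
        ok = (dist_v <= delta).all(axis=1)
        w = np.exp(-(dist_v**2) / (2.0 * sigma_g**2)) / (sigma_g * np.sqrt(2 * np.pi))
        dv = dvals[tris[best_tri]]  # (n, 3, 3)
        num = (w[..., None] * dv).sum(axis=1)
        den = w.sum(axis=1)
        vals = np.where(ok[:, None], num / den[:, None], 0.0)
        out[idx] = vals
    return DisplacementField(grid, out.reshape(grid.shape + (3,)))


# --------------------------------------------------------------------------
# fusion
# --------------------------------------------------------------------------


def fuse_labels_majority(
    warped_maps: list[TissueProbMap], weights: list[float]
) -> LabelVolume:
    """Weighted majority vote over per-subject argmax tissue classes.

    Per voxel and subject, the argmax class among (WM, GM, CSF, background)
    receives the subject's weight; ties in both the per-subject argmax and
    the final vote resolve by the fixed priority WM > GM > CSF > background.
    """
    if not warped_maps:
        raise ValidationError("no maps to fuse")
    weights = np.asarray(list(weights), dtype=float)
    if len(weights) != len(warped_maps) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValidationError("weights must be >= 0 with positive sum")
    grid = warped_maps[0].grid
    votes = np.zeros(grid.shape + (4,))  # order: WM, GM, CSF, background
    for m, w in zip(warped_maps, weights):
        grid.require_compatible(m.grid)
        stack = np.concatenate([m.channels, m.background[..., None]], axis=-1)
        cls = np.argmax(stack, axis=-1)  # first max -> WM priority
        for c in range(4):
            votes[..., c] += w * (cls == c)
    winner = np.argmax(votes, axis=-1)
    code = np.array([3, 2, 1, 0])  # WM, GM, CSF, background label codes
    return LabelVolume(grid, code[winner].astype(np.int16))


def fuse_intensity(
    warped_images: list[ScalarVolume], weights: list[float]
) -> ScalarVolume:
    """Voxelwise weighted mean of intensity images."""
    if not warped_images:
        raise ValidationError("no images to fuse")
    weights = np.asarray(list(weights), dtype=float)
    if len(weights) != len(warped_images) or weights.sum() <= 0:
        raise ValidationError("weights must have positive sum")
    grid = warped_images[0].grid
    acc = np.zeros(grid.shape)
    for img, w in zip(warped_images, weights):
        grid.require_compatible(img.grid)
        acc += w * img.values
    return ScalarVolume(grid, acc / weights.sum())


def fuse_tissue_probability(
    warped_maps: list[TissueProbMap], weights: list[float]
) -> TissueProbMap:
    weights = np.asarray(list(weights), dtype=float)
    grid = warped_maps[0].grid
    acc = np.zeros(grid.shape + (3,))
    for m, w in zip(warped_maps, weights):
        acc += w * m.channels
    return TissueProbMap(grid, np.clip(acc / weights.sum(), 0.0, 1.0))


# --------------------------------------------------------------------------
# end-to-end reference atlas
# --------------------------------------------------------------------------


def total_pullback_field(
    affine: AffineTransform, phi: DisplacementField
) -> DisplacementField:
    """Single pull-back field equivalent to: resample by phi, then affine.

    out(x) = moving(affine^{-1}(x + phi(x))); the combined displacement is
    affine^{-1}(x + phi(x)) - x on phi's grid.
    """
    grid = phi.grid
    x = grid.world_coords()
    inv = affine.inverse()
    target = inv.apply((x + phi.vectors).reshape(-1, 3)).reshape(x.shape)
    return DisplacementField(grid, target - x)


def _warp_surfaces_inverse(
    surfaces: dict[str, HemiSurfaces], phi: DisplacementField, affine: AffineTransform
) -> dict[str, HemiSurfaces]:
    """Registered subject surfaces in atlas space.

    Vertices map forward with the affine and then with the inverse of the
    pull-back field (surfaces move with the inverse of the resampling map).
    Fields with folds far from the anatomy fall back to a pseudo-inverse
    whose residual is verified at the surface vertices.
    """
    from .data_model import (
        ConvergenceError,
        invert_displacement_best_effort,
        inversion_residual_at,
    )

    try:
        psi = invert_displacement(phi, max_iter=60, tol=1e-3)
    except ConvergenceError:
        psi = invert_displacement_best_effort(phi)
    tol_mm = 0.5 * float(min(phi.grid.spacing))
    out = {}
    for hemi, hs in surfaces.items():
        meshes = {}
        for name, mesh in (("white", hs.white), ("pial", hs.pial)):
            v = affine.apply(mesh.vertices)
            resid = inversion_residual_at(phi, psi, v)
            if resid.mean() > tol_mm:
                raise ConvergenceError(
                    f"inverse field inaccurate at {hemi} {name} surface "
                    f"(mean residual {resid.mean():.2f} mm)"
                )
            v = v + sample_vectors(psi.vectors, psi.grid, v)
            meshes[name] = TriangleMesh(v, mesh.triangles.copy())
        out[hemi] = HemiSurfaces(meshes["white"], meshes["pial"])
    return out


def _resample_to_reference_indexing(
    reg: _PerScanReg,
    warped_surfaces: dict[str, HemiSurfaces],
    ref_spheres: dict[str, SphericalMap],
) -> dict[str, HemiSurfaces]:
    """Express a subject's registered surfaces on the reference vertex indexing.

    The spherical warp places each moving vertex on the reference sphere;
    interpolating the registered anatomical coordinates at the reference
    sphere's own vertices yields correspondence-resampled surfaces.
    """
    out = {}
    for hemi, hs in warped_surfaces.items():
        if hemi not in reg.warp_by_hemi:
            out[hemi] = hs.copy()
            continue
        warp, ref_sphere = reg.warp_by_hemi[hemi][0], reg.warp_by_hemi[hemi][1]
        src = SphericalMap(warp.target_positions, hs.white.triangles)
        meshes = {}
        for name, mesh in (("white", hs.white), ("pial", hs.pial)):
            coords = resample_attribute_on_sphere(
                src, mesh.vertices, ref_sphere.positions
            )
            meshes[name] = TriangleMesh(coords, ref_sphere.triangles.copy())
        out[hemi] = HemiSurfaces(meshes["white"], meshes["pial"])
    return out


@dataclass
class ReferenceAtlasResult:
    bundle: AtlasBundle
    total_fields: dict  # scan key -> DisplacementField (incl. affine)
    weights: dict  # scan key -> temporal weight
    reference_key: tuple
    # decomposition of each total field (the affine part must be inverted
    # analytically; it grows linearly at the grid corners)
    affines: dict = field(default_factory=dict)  # scan key -> AffineTransform
    nl_fields: dict = field(default_factory=dict)  # scan key -> DisplacementField


def build_reference_atlas(
    scans: list[SubjectScan],
    params: ScdemParams | None = None,
    kernel: TemporalKernel | None = None,
    center: float = 12.0,
    n_rounds: int = 2,
    use_surfaces: bool = True,
    sphere_opts: dict | None = None,
    correspondences: dict | None = None,
) -> ReferenceAtlasResult:
    """Task (i): the reference surface-volume atlas at `center` months.

    `correspondences` optionally injects precomputed spherical warps per
    scan key and hemisphere, bypassing the internal spherical registration.
    """
    if not scans:
        raise ValidationError("empty cohort")
    params = params or ScdemParams()
    kernel = kernel or TemporalKernel()

    regs, fused_ref, ref_scan = groupwise_register(
        scans, params, n_rounds=n_rounds, use_surfaces=use_surfaces,
        sphere_opts=sphere_opts, correspondences=correspondences,
    )
    grid = ref_scan.tissue.grid
    weights = {s.key: kernel.weight(s.age_months, center) for s in scans}

    # registered surfaces on shared (reference) indexing
    ref_spheres = {}
    some_reg = regs[scans[0].key]
    for hemi, tup in some_reg.warp_by_hemi.items():
        ref_spheres[hemi] = tup[1]

    registered, ages = [], []
    resampled_by_key = {}
    for s in scans:
        r = regs[s.key]
        warped = _warp_surfaces_inverse(s.surfaces, r.phi, r.affine)
        res = (
            _resample_to_reference_indexing(r, warped, ref_spheres)
            if r.warp_by_hemi
            else warped
        )
        resampled_by_key[s.key] = res
        registered.append(res)
        ages.append(s.age_months)

    atlas_surfaces = build_surface_atlas(registered, ages, kernel, center)

    # per-scan corrective displacement from surface residuals (Gaussian
    # vertex weighting, hard delta cutoff) and total field phi + delta-phi
    warped_tissue, warped_t1, warped_t2 = [], [], []
    total_fields, affines, nl_fields = {}, {}, {}
    for s in scans:
        r = regs[s.key]
        res = resampled_by_key[s.key]
        if use_surfaces and r.warp_by_hemi:
            disp = {}
            for hemi in atlas_surfaces:
                for name in ("white", "pial"):
                    subj = getattr(res[hemi], name).vertices
                    atl = getattr(atlas_surfaces[hemi], name).vertices
                    disp[(hemi, name)] = subj - atl
            dphi = corrective_displacement(atlas_surfaces, disp, grid)
            phi_tot = DisplacementField(grid, r.phi.vectors + dphi.vectors)
        else:
            phi_tot = r.phi
        total = total_pullback_field(r.affine, phi_tot)
        total_fields[s.key] = total
        affines[s.key] = r.affine
        nl_fields[s.key] = phi_tot
        warped_tissue.append(warp_tissue_map(s.tissue, total))
        warped_t1.append(warp_scalar_volume(s.t1w, total))
        warped_t2.append(warp_scalar_volume(s.t2w, total))

    wlist = [weights[s.key] for s in scans]
    bundle = AtlasBundle(
        age_months=center,
        t1w=fuse_intensity(warped_t1, wlist),
        t2w=fuse_intensity(warped_t2, wlist),
        tissue_prob=fuse_tissue_probability(warped_tissue, wlist),
        tissue_label=fuse_labels_majority(warped_tissue, wlist),
        surfaces=atlas_surfaces,
    )
    return ReferenceAtlasResult(
        bundle, total_fields, weights, ref_scan.key, affines, nl_fields
    )
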