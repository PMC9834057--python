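"""Self-contained validation experiments at desk scale.

Each function builds its own synthetic inputs (deterministic under `seed`),
runs the relevant part of the pipeline, and returns the measured quantities
as a flat dict.  They are shared by the acceptance test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter

from .atlas import (
    TemporalKernel,
    build_reference_atlas,
    corrective_displacement,
    fuse_labels_majority,
    groupwise_register,
)
from .data_model import (
    DisplacementField,
    TissueProbMap,
    invert_displacement,
    sample_scalar,
    sample_vectors,
    warp_tissue_map,
)
from .longitudinal import (
    LongitudinalPair,
    build_all_months,
    kernel_regress_fields,
    parallel_transport,
)
from .scdem import ScdemParams, register_pair, solve_scdem
from .sphere_reg import SphericalWarp, register_spherical_maps
from .subjects import HemiSurfaces
from .surface import (
    SphericalMap,
    TriangleMesh,
    cortical_thickness,
    mean_curvature,
    surface_area,
)
from .synth import (
    CohortSpec,
    GrowthModel,
    LogisticCurve,
    _real_sph_harm,
    default_grid,
    make_blob_phantom,
    make_icosphere,
    make_known_deformation,
    make_longitudinal_cohort,
    make_phantom,
)

log = logging.getLogger(__name__)

# solver settings used by the recovery experiments: a short coarse-to-fine
# continuation on map smoothness, then a low-stiffness polish
RECOVERY_SCHEDULE = [
    (2.0, 150, 0.12, 8.0),
    (1.0, 150, 0.12, 8.0),
    (0.0, 400, 0.12, 8.0),
    (0.0, 200, 0.05, 8.0),
]

#: default pipeline solver parameters (see docs/methods.md for calibration)
PIPELINE_PARAMS = dict(alpha=0.15, beta=8.0, gamma=1.0, damping=0.25, max_steps=150,
                       force_tol=1e-4)


def _smooth_map(m: TissueProbMap, sig: float) -> TissueProbMap:
    c = np.stack([gaussian_filter(m.channels[..., i], sig) for i in range(3)], -1)
    return TissueProbMap(m.grid, np.clip(c, 0.0, 1.0))


def solve_with_continuation(moving, fixed, constraints=None, schedule=RECOVERY_SCHEDULE,
                            gamma: float = 0.0):
    """Run solve_scdem through a map-smoothing continuation schedule."""
    phi_v = None
    for sig, steps, a, b in schedule:
        mv = _smooth_map(moving, sig) if sig > 0 else moving
        fx = _smooth_map(fixed, sig) if sig > 0 else fixed
        p = ScdemParams(alpha=a, beta=b, gamma=gamma, damping=0.25,
                        max_steps=steps, force_tol=1e-6)
        phi = solve_scdem(mv, fx, constraints, p, phi0=phi_v)
        phi_v = phi.vectors
    return DisplacementField(moving.grid, phi_v)


# --------------------------------------------------------------------------
# A1: known-deformation recovery
# --------------------------------------------------------------------------


def exp_known_deformation(seed: int = 7) -> dict:
    """Warp a two-tissue blob phantom by a known smooth field (max 4 voxels)
    and measure how well volumetric-only SC-DEM recovers it."""
    grid = default_grid(48, 2.0)
    fixed = make_blob_phantom(grid, seed=seed)
    truth = make_known_deformation(grid, max_mm=8.0, smoothness_mm=20.0, seed=seed + 100)
    moving = warp_tissue_map(fixed, truth)
    inv_truth = invert_displacement(truth, max_iter=100, tol=1e-4)
    phi = solve_with_continuation(moving, fixed)
    fg = fixed.channels.sum(-1) > 0.1
    epe_vox = np.linalg.norm(phi.vectors - inv_truth.vectors, axis=-1) / grid.spacing[0]
    return {
        "recovery_mean_epe_vox": float(epe_vox[fg].mean()),
        "recovery_truth_mean_vox": float(
            (np.linalg.norm(inv_truth.vectors, axis=-1) / grid.spacing[0])[fg].mean()
        ),
        "n": int(fg.sum()),
    }


# --------------------------------------------------------------------------
# A2: surface-constraint efficacy
# --------------------------------------------------------------------------


def _white_surface_error(scan_m, scan_f, affine, phi) -> float:
    """Mean white-vertex correspondence error after registration.

    The pull-back deformation maps a fixed-frame point to its moving-frame
    source; with perfect registration each fixed white vertex maps onto the
    affine-aligned moving white vertex of the same index (the phantoms share
    indexing), so the error is |Phi(v_fixed) - affine(v_moving)|.
    """
    errs = []
    for hemi in scan_m.surfaces:
        v_f = scan_f.surfaces[hemi].white.vertices
        mapped = v_f + sample_vectors(phi.vectors, phi.grid, v_f)
        v_m = affine.apply(scan_m.surfaces[hemi].white.vertices)
        errs.append(np.linalg.norm(mapped - v_m, axis=1).mean())
    return float(np.mean(errs))


def exp_surface_constraint(seed: int = 11) -> dict:
    """Register a folded phantom pair with and without the surface force and
    compare white-surface vertex errors (gamma > 0 should reduce them).

    Predetermined surface displacements use the phantoms' exact shared-index
    correspondences, so the experiment isolates the surface force itself
    (spherical-registration accuracy is measured separately)."""
    from .scdem import spherical_map_of

    grid = default_grid(48, 2.0)
    growth = GrowthModel(noise_sd=0.0)
    scan_f = make_phantom(12.0, growth, grid, seed=seed, subject_id="fix")
    scan_m = make_phantom(12.0, growth, grid, seed=seed + 1, subject_id="mov")
    exact_warps = {}
    for hemi, hs in scan_f.surfaces.items():
        sm = spherical_map_of(hs.white)
        exact_warps[hemi] = (SphericalWarp(sm.positions.copy()), sm)
    base = dict(PIPELINE_PARAMS)
    errs = {}
    for gamma in (0.0, PIPELINE_PARAMS["gamma"]):
        params = ScdemParams(**{**base, "gamma": gamma, "max_steps": 250})
        affine, phi = register_pair(
            scan_m, scan_f, params, use_surfaces=gamma > 0,
            precomputed_warps=exact_warps if gamma > 0 else None,
        )
        errs[gamma] = _white_surface_error(scan_m, scan_f, affine, phi)
    g = PIPELINE_PARAMS["gamma"]
    reduction = 100.0 * (errs[0.0] - errs[g]) / errs[0.0]
    return {
        "surface_error_gamma0_mm": errs[0.0],
        "surface_error_gamma_mm": errs[g],
        "surface_error_reduction_pct": float(reduction),
        "n": len(scan_f.surfaces[next(iter(scan_f.surfaces))].white.vertices),
    }


# --------------------------------------------------------------------------
# A3: corrective-displacement oracle equivalence
# --------------------------------------------------------------------------


def corrective_displacement_oracle(verts, tris, dvals, grid, sigma_g=3.0, delta=6.0):
    """Literal exhaustive evaluation of the corrective-displacement formula."""
    from .atlas import _point_triangle_distance

    x = grid.world_coords().reshape(-1, 3)
    out = np.zeros_like(x)
    for i, p in enumerate(x):
        pr = np.broadcast_to(p, (len(tris), 3))
        d2, _ = _point_triangle_distance(
            pr.copy(), verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
        )
        t = int((d2 <= d2.min() + 1e-12).argmax())  # smallest index among ties
        corners = verts[tris[t]]
        dist = np.linalg.norm(corners - p, axis=1)
        if np.all(dist <= delta):
            w = np.exp(-(dist**2) / (2 * sigma_g**2)) / (sigma_g * np.sqrt(2 * np.pi))
            out[i] = (w[:, None] * dvals[tris[t]]).sum(0) / w.sum()
    return out.reshape(grid.shape + (3,))


def exp_corrective_oracle(seed: int = 3) -> dict:
    """Fast corrective displacement vs the exhaustive nearest-triangle oracle
    on a 16^3 grid and a ~100-vertex surface."""
    rng = np.random.default_rng(seed)
    grid = default_grid(16, 2.0)
    ico = make_icosphere(2, 10.0)  # 162 vertices
    keep = ico  # closed surface, ~100-vertex scale
    dvals = rng.normal(0.0, 1.5, size=(len(keep.vertices), 3))
    white = TriangleMesh(keep.vertices.copy(), keep.triangles.copy())
    pial = TriangleMesh(keep.vertices * 1.001, keep.triangles.copy())
    surfaces = {"lh": HemiSurfaces(white, pial)}
    disp = {("lh", "white"): dvals, ("lh", "pial"): dvals}
    fast = corrective_displacement(surfaces, disp, grid)

    from .atlas import _pool_surfaces

    v, t, d = _pool_surfaces(surfaces, disp)
    oracle = corrective_displacement_oracle(v, t, d, grid)
    diff = np.abs(fast.vectors - oracle).max()

    # voxels beyond delta from any vertex of their closest triangle: exact 0
    x = grid.world_coords().reshape(-1, 3)
    from scipy.spatial import cKDTree

    dist_any = cKDTree(v).query(x)[0]
    far = dist_any > 6.0 + 1e-9
    far_max = np.abs(fast.vectors.reshape(-1, 3)[far]).max() if far.any() else 0.0
    return {
        "corrective_oracle_max_diff_mm": float(diff),
        "corrective_far_voxel_max_mm": float(far_max),
        "n": int(np.prod(grid.shape)),
    }


# --------------------------------------------------------------------------
# A4: parallel-transport oracle
# --------------------------------------------------------------------------


def _pointwise_inverse(field: DisplacementField, pts: np.ndarray, iters: int = 60):
    """Independent per-point fixed-point inversion used only as an oracle."""
    psi = -sample_vectors(field.vectors, field.grid, pts)
    for _ in range(iters):
        psi = -sample_vectors(field.vectors, field.grid, pts + psi)
    return psi


def exp_transport_oracle(seed: int = 5) -> dict:
    """Parallel transport vs a brute-force pointwise three-map-chain oracle
    on a 16^3 grid, plus the two identity limits."""
    grid = default_grid(16, 2.0)
    phi_long = make_known_deformation(grid, 1.6, 10.0, seed=seed)
    phi_atlas = make_known_deformation(grid, 1.6, 10.0, seed=seed + 1)
    pair = LongitudinalPair("s", 6.0, 12.0, phi_long, phi_atlas)
    par = parallel_transport(pair, tol=1e-4)

    x = grid.world_coords().reshape(-1, 3)
    y = x + sample_vectors(phi_atlas.vectors, grid, x)
    z = y + sample_vectors(phi_long.vectors, grid, y)
    w = z + _pointwise_inverse(phi_atlas, z)
    oracle = (w - x).reshape(grid.shape + (3,))
    interior = np.zeros(grid.shape, dtype=bool)
    interior[2:-2, 2:-2, 2:-2] = True
    chain_err_vox = (
        np.abs(par.vectors - oracle)[interior].max() / grid.spacing[0]
    )

    ident_atlas = LongitudinalPair(
        "s", 6.0, 12.0, phi_long, DisplacementField.zeros(grid)
    )
    e_ident = np.abs(parallel_transport(ident_atlas).vectors - phi_long.vectors).max()
    ident_long = LongitudinalPair(
        "s", 6.0, 12.0, DisplacementField.zeros(grid), phi_atlas
    )
    e_long = np.abs(parallel_transport(ident_long, tol=1e-4).vectors[interior]).max()
    return {
        "transport_chain_max_err_vox": float(chain_err_vox),
        "transport_identity_conjugation_err_mm": float(e_ident),
        "transport_identity_longitudinal_err_mm": float(e_long),
        "n": int(interior.sum()),
    }


# --------------------------------------------------------------------------
# A5: kernel-regression reduction
# --------------------------------------------------------------------------


def exp_kernel_regression(seed: int = 9) -> dict:
    """Single-pair kernel regression returns that pair's field; the
    normalized weight vector sums to one."""
    grid = default_grid(12, 2.0)
    f = make_known_deformation(grid, 1.0, 8.0, seed=seed)
    pair = LongitudinalPair(
        "s", 5.5, 12.0, f, DisplacementField.zeros(grid), transported=f
    )
    out = kernel_regress_fields([pair], tau0=5.0)
    single_err = np.abs(out.vectors - f.vectors).max()

    kern = TemporalKernel()
    pairs = []
    rng = np.random.default_rng(seed)
    for i, (tp, t) in enumerate([(4.5, 11.0), (5.5, 12.0), (6.0, 13.0)]):
        ff = make_known_deformation(grid, 1.0, 8.0, seed=seed + i)
        pairs.append(
            LongitudinalPair(f"s{i}", tp, t, ff, DisplacementField.zeros(grid), transported=ff)
        )
    w = np.array([kern.weight(p.tau_prime, 5.0) * kern.weight(p.tau, 12.0) for p in pairs])
    wn = w / w.sum()
    manual = sum(wi * p.transported.vectors for wi, p in zip(wn, pairs))
    multi = kernel_regress_fields(pairs, tau0=5.0, kernel=kern)
    formula_err = np.abs(multi.vectors - manual).max()
    return {
        "regression_single_pair_err_mm": float(single_err),
        "regression_weight_sum_dev": float(abs(wn.sum() - 1.0)),
        "regression_formula_max_err_mm": float(formula_err),
        "n": len(pairs),
    }


# --------------------------------------------------------------------------
# A6: atlas sharpness
# --------------------------------------------------------------------------


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / s) if s else 1.0


def exp_atlas_sharpness(seed: int = 13, n_copies: int = 10) -> dict:
    """Fuse randomly deformed copies of one phantom with and without
    registration and compare WM Dice against the ground-truth phantom.

    Uses the blob validation phantom: its dense, isotropically oriented
    interfaces make the random deformations fully observable, so groupwise
    registration with reference de-biasing can recover the barycenter."""
    from .data_model import ScalarVolume
    from .subjects import SubjectScan

    grid = default_grid(48, 2.0)
    base = make_blob_phantom(grid, seed=seed)
    truth_wm = base.channels[..., 0] > 0.5
    zero = ScalarVolume(grid, np.zeros(grid.shape))

    copies = []
    for i in range(n_copies):
        fld = make_known_deformation(grid, 5.0, 16.0, seed=seed + 10 + i)
        copies.append(
            SubjectScan(f"c{i:02d}", 12.0, zero, zero, warp_tissue_map(base, fld))
        )

    weights = [1.0] * n_copies
    unreg = fuse_labels_majority([c.tissue for c in copies], weights)
    dice_unreg = _dice(unreg.labels == 3, truth_wm)

    params = ScdemParams(**{**PIPELINE_PARAMS, "gamma": 0.0})
    regs, fused_ref, ref = groupwise_register(
        copies, params, n_rounds=1, use_surfaces=False
    )
    warped = [
        warp_tissue_map(regs[c.key].moved_tissue, regs[c.key].phi) for c in copies
    ]
    fused = fuse_labels_majority(warped, weights)
    dice_reg = _dice(fused.labels == 3, truth_wm)
    return {
        "atlas_wm_dice_registered": dice_reg,
        "atlas_wm_dice_unregistered": dice_unreg,
        "n": n_copies,
    }


# --------------------------------------------------------------------------
# A7: analytic geometry
# --------------------------------------------------------------------------


def exp_geometry() -> dict:
    """Icosphere area, mean curvature and concentric-sphere thickness against
    their analytic values."""
    ico = make_icosphere(4, 1.0)
    area_rel_err = abs(surface_area(ico) - 4 * np.pi) / (4 * np.pi)
    H = mean_curvature(ico)
    curv_med_err = float(np.median(np.abs(H - 1.0)))
    w = make_icosphere(3, 1.0)
    p = make_icosphere(3, 1.5)
    th = cortical_thickness(w, p)
    th_rel_err = float(np.abs(th - 0.5).max() / 0.5)
    return {
        "icosphere_area_rel_err": float(area_rel_err),
        "curvature_median_err": curv_med_err,
        "thickness_rel_err": th_rel_err,
        "n": ico.n_vertices(),
    }


# --------------------------------------------------------------------------
# A8: spherical registration rotation recovery
# --------------------------------------------------------------------------


def _smooth_attr(dirs: np.ndarray, terms) -> np.ndarray:
    f = np.zeros(len(dirs))
    for l, m, c in terms:
        f += c * _real_sph_harm(l, m, dirs)
    return f


def exp_spherical_rotation(angle_deg: float = 10.0) -> dict:
    """Recover a known rotation of the attribute pattern on an icosphere."""
    ico = make_icosphere(4, 1.0)
    pos = ico.vertices
    conv_terms = ((2, 1, 1.0), (3, 2, 0.8), (4, 1, 0.5))
    curv_terms = ((3, 1, 1.0), (4, 3, 0.7))
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])

    fixed = SphericalMap(
        pos.copy(), ico.triangles.copy(),
        convexity=_smooth_attr(pos, conv_terms),
        curvature=_smooth_attr(pos, curv_terms),
    )
    # moving vertex u carries the attribute the fixed map has at R @ u
    moving = SphericalMap(
        pos.copy(), ico.triangles.copy(),
        convexity=_smooth_attr(pos @ R.T, conv_terms),
        curvature=_smooth_attr(pos @ R.T, curv_terms),
    )
    warp = register_spherical_maps(moving, fixed)
    target = pos @ R.T
    dots = np.clip((warp.target_positions * target).sum(1), -1, 1)
    geo = np.arccos(dots)
    edges = np.unique(
        np.sort(ico.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1), axis=0
    )
    mean_edge = np.linalg.norm(pos[edges[:, 0]] - pos[edges[:, 1]], axis=1).mean()

    ident = register_spherical_maps(fixed, fixed)
    ident_motion = np.linalg.norm(ident.target_positions - pos, axis=1).max()
    return {
        "spherical_mean_geodesic_err": float(geo.mean()),
        "spherical_mean_edge_len": float(mean_edge),
        "spherical_err_over_edge": float(geo.mean() / mean_edge),
        "spherical_identity_max_motion": float(ident_motion),
        "n": len(pos),
    }


# --------------------------------------------------------------------------
# A9: GAMM recovery
# --------------------------------------------------------------------------


def exp_gamm_recovery(seed: int = 1, n_subjects: int = 40) -> dict:
    """Logistic growth + random intercepts: fitted-curve RMSE (at the design's
    observed ages), intercept-variance recovery and peak-growth-age error."""
    import pandas as pd

    from .trajectories import FeatureTable, fit_gamm, velocity_and_peak

    curve = LogisticCurve(10.0, 20.0, 0.35, 8.0)
    rangev = float(curve(24.0) - curve(0.5))
    noise_sd = 0.05 * rangev
    int_sd = 0.10 * rangev
    schedules = ([0.5, 3.5, 6.5, 9.5, 12.5, 24.0], [2.0, 5.0, 8.0, 11.0, 14.0, 24.0])
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        ages = schedules[i % 2]
        gi = rng.normal(0.0, int_sd)
        for t in ages:
            rows.append(
                dict(subject=f"s{i:02d}", age_months=t, feature="f",
                     value=float(curve(t)) + gi + rng.normal(0.0, noise_sd))
            )
    df = pd.DataFrame(rows)
    fit = fit_gamm(FeatureTable(df), "f", k=8)
    obs = np.unique(df["age_months"])
    rmse = float(np.sqrt(np.mean((fit.predict(obs) - curve(obs)) ** 2)))
    _, _, peak = velocity_and_peak(fit)
    return {
        "gamm_curve_rmse": rmse,
        "gamm_noise_sd": noise_sd,
        "gamm_intercept_var": float(fit.intercept_variance),
        "gamm_intercept_var_true": int_sd**2,
        "gamm_peak_age_err_months": float(abs(peak - curve.peak_velocity_age)),
        "n": n_subjects,
    }


# --------------------------------------------------------------------------
# A10/A11: end-to-end spatiotemporal atlas
# --------------------------------------------------------------------------


def white_interface_distance(bundle) -> float:
    """Mean |WM probability - 0.5| crossing distance: for each white vertex,
    distance along the local probability gradient to the 0.5 level of the
    fused WM+ventricle volume, approximated by |p - 0.5| / |grad p|."""
    prob = bundle.tissue_prob.channel("WM")
    grid = bundle.tissue_prob.grid
    gr = np.stack(np.gradient(prob, *grid.spacing), axis=-1)
    dists = []
    for hemi, hs in bundle.surfaces.items():
        v = hs.white.vertices
        p = sample_scalar(prob, grid, v)
        g = sample_vectors(gr, grid, v)
        gn = np.linalg.norm(g, axis=1)
        ok = gn > 1e-3
        dists.append(np.abs(p[ok] - 0.5) / gn[ok])
    return float(np.concatenate(dists).mean())


def run_end_to_end(seed: int = 0, n_subjects: int = 12,
                   months: list | None = None) -> dict:
    """Simulate a cohort, build the reference atlas, propagate to all months,
    and score the result against the generator's prescribed growth."""
    months = months if months is not None else [float(m) for m in range(1, 25)]
    growth = GrowthModel()
    grid = default_grid(48, 2.0)
    spec = CohortSpec(n_subjects=n_subjects, seed=seed)
    scans = make_longitudinal_cohort(spec, growth, grid)

    kernel = TemporalKernel()
    params = ScdemParams(**PIPELINE_PARAMS)
    window = [s for s in scans if 10.5 <= s.age_months <= 13.5]
    ref = build_reference_atlas(window, params, kernel, center=12.0, n_rounds=1)

    # longitudinal pairs: every other visit of each in-window subject
    by_subject: dict = {}
    for s in scans:
        by_subject.setdefault(s.subject_id, []).append(s)
    pairs = []
    sphere_cache: dict = {}

    def spheres_of(scan):
        # same-subject phantoms share vertex indexing, so the exact spherical
        # correspondence (identity) is supplied instead of re-registering
        from .scdem import spherical_map_of

        if scan.key not in sphere_cache:
            warps = {}
            for hemi, hs in scan.surfaces.items():
                sm = spherical_map_of(hs.white)
                warps[hemi] = (SphericalWarp(sm.positions.copy()), sm)
            sphere_cache[scan.key] = warps
        return sphere_cache[scan.key]

    for s_tau in window:
        phi_atlas = ref.total_fields[s_tau.key]
        for s_tp in by_subject[s_tau.subject_id]:
            from .atlas import total_pullback_field
            from .data_model import AffineTransform

            if s_tp.age_months == s_tau.age_months:
                phi_long = DisplacementField.zeros(grid)
                aff_l, phi_l = AffineTransform.identity(), phi_long
            else:
                # moving = the tau scan, fixed = the tau' scan: the induced
                # point map sends tau'-frame points to their aged positions
                aff_l, phi_l = register_pair(
                    s_tau, s_tp, params, use_surfaces=True,
                    precomputed_warps=spheres_of(s_tp),
                )
                phi_long = total_pullback_field(aff_l, phi_l)
            p = LongitudinalPair(
                s_tau.subject_id, s_tp.age_months, s_tau.age_months,
                phi_long, phi_atlas, scan_prime=s_tp,
                atlas_affine=ref.affines[s_tau.key],
                atlas_nl=ref.nl_fields[s_tau.key],
                long_affine=aff_l, long_nl=phi_l,
            )
            p.transported = parallel_transport(p)
            pairs.append(p)

    result = build_all_months(pairs, ref.bundle, months, kernel)

    produced = sorted(result.months)
    gm_curve = np.array([result.months[m].tissue_volumes_ml()["GM"] for m in produced])
    prescribed = np.array([float(growth.volume_ml("GM", m)) for m in produced])
    r = float(np.corrcoef(gm_curve, prescribed)[0, 1])
    wbv = np.array([result.months[m].tissue_volumes_ml()["WBV"] for m in produced])
    inversions = int((np.diff(wbv) < 0).sum())
    iface = {m: white_interface_distance(result.months[m]) for m in produced}
    vox = grid.spacing[0]
    return {
        "e2e_gm_pearson_r": r,
        "e2e_reference_iface_dist_vox": white_interface_distance(ref.bundle) / vox,
        "e2e_max_month_iface_dist_vox": max(iface.values()) / vox,
        "e2e_wbv_inversions": inversions,
        "e2e_months_covered": len(produced),
        "e2e_months_requested": len(months),
        "n": n_subjects,
    }
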