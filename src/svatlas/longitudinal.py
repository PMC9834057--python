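"""Longitudinal atlas construction by parallel transport and kernel regression.

Intra-subject growth deformations (visit tau' -> visit tau in the reference
window) are re-expressed in atlas space by conjugation with the
subject-to-atlas map,

    Phi_par = Phi_to_atlas^{-1} o Phi_long o Phi_to_atlas

(rightmost map applied first), kernel-regressed across the cohort with
weights w(tau', tau0) * w(tau, 12), and used to propagate the reference
atlas to each requested month.  Volumes are resampled with the regressed
pull-back field; surface vertices move with its inverse, so surfaces and
volumes stay mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atlas import AgeWindow, TemporalKernel, fuse_intensity
from .data_model import (
    DisplacementField,
    ScalarVolume,
    ValidationError,
    compose_displacements,
    invert_displacement,
    sample_vectors,
    warp_label_volume,
    warp_scalar_volume,
    warp_tissue_map,
)
from .subjects import AtlasBundle, HemiSurfaces, SubjectScan
from .surface import TriangleMesh

__all__ = [
    "LongitudinalPair",
    "CoverageError",
    "parallel_transport",
    "kernel_regress_fields",
    "propagate_atlas",
    "build_month_intensity_atlas",
    "build_all_months",
    "MonthAtlasResult",
]

log = logging.getLogger(__name__)


class CoverageError(RuntimeError):
    """No eligible longitudinal pairs cover the requested age."""


@dataclass
class LongitudinalPair:
    """One transported longitudinal deformation.

    phi_long: pull-back field of the tau' -> tau registration (on the tau
    scan's grid, affine folded in); phi_to_atlas: pull-back field of the
    tau scan -> reference atlas registration (affine folded in).
    """

    subject_id: str
    tau_prime: float
    tau: float
    #: pull-back field on the tau' grid from registering the tau scan
    #: (moving) onto the tau' scan (fixed): the induced point map
    #: Phi_L = id + phi_long sends a tau'-frame point to its tau-frame
    #: (aged) counterpart, so conjugation transports *growth*
    phi_long: DisplacementField
    phi_to_atlas: DisplacementField
    transported: DisplacementField | None = None
    scan_prime: SubjectScan | None = None
    # optional decomposition of the two maps into affine + nonlinear parts;
    # with it the conjugation evaluates the affine factors analytically and
    # extends gracefully beyond the grid (a combined field grows linearly at
    # the corners, where zero-extension sampling and fixed-point inversion
    # both break down)
    atlas_affine: object | None = None  # AffineTransform
    atlas_nl: DisplacementField | None = None
    long_affine: object | None = None  # AffineTransform
    long_nl: DisplacementField | None = None

    def __post_init__(self):
        self.phi_long.grid.require_compatible(self.phi_to_atlas.grid)


def parallel_transport(
    pair: LongitudinalPair, max_iter: int = 60, tol: float = 1e-3
) -> DisplacementField:
    """Conjugate the longitudinal deformation into atlas space.

    Phi_par = Phi_A^{-1} o Phi_L o Phi_A with Phi_A = id + phi_to_atlas and
    Phi_L = id + phi_long; built from one fixed-point inversion and two
    compositions (rightmost map applied first).  When the pair carries the
    affine/nonlinear decomposition of phi_to_atlas, the affine factor of the
    inverse is computed analytically.
    """
    decomposed = (
        pair.atlas_affine is not None
        and pair.atlas_nl is not None
        and pair.long_affine is not None
        and pair.long_nl is not None
    )
    if decomposed:
        from .data_model import ConvergenceError, invert_displacement_best_effort

        grid = pair.phi_to_atlas.grid
        aff_a, nl_a = pair.atlas_affine, pair.atlas_nl
        aff_l, nl_l = pair.long_affine, pair.long_nl
        try:
            inv_nl_a = invert_displacement(nl_a, max_iter=max_iter, tol=tol)
        except ConvergenceError as exc:
            # surface-driven fields may fold locally; the pseudo-inverse is
            # accurate wherever the field is contractive
            log.info("transport using pseudo-inverse for %s (%s)", pair.subject_id, exc)
            inv_nl_a = invert_displacement_best_effort(nl_a)
        x = grid.world_coords().reshape(-1, 3)
        # pointwise chain with analytic affine factors, so the maps extend
        # as pure affines beyond the grid (nl parts zero-extend)
        y = aff_a.inverse().apply(x + sample_vectors(nl_a.vectors, grid, x))
        z = aff_l.inverse().apply(y + sample_vectors(nl_l.vectors, grid, y))
        u = aff_a.apply(z)
        w = u + sample_vectors(inv_nl_a.vectors, grid, u)
        return DisplacementField(grid, (w - x).reshape(grid.shape + (3,)))
    inv_a = invert_displacement(pair.phi_to_atlas, max_iter=max_iter, tol=tol)
    inner = compose_displacements(pair.phi_long, pair.phi_to_atlas)
    return compose_displacements(inv_a, inner)


def _eligible(pairs, tau0: float, w_tau0: AgeWindow, w_ref: AgeWindow):
    return [
        p
        for p in pairs
        if w_tau0.contains(p.tau_prime) and w_ref.contains(p.tau)
    ]


def kernel_regress_fields(
    pairs: list[LongitudinalPair],
    tau0: float,
    kernel: TemporalKernel | None = None,
    ref_center: float = 12.0,
    half_width: float = 1.5,
) -> DisplacementField:
    """Weighted average of transported fields (weights w(tau',tau0)*w(tau,12)).

    Pairs outside either age window are excluded before weighting.
    """
    kernel = kernel or TemporalKernel()
    w_tau0 = AgeWindow(tau0, half_width)
    w_ref = AgeWindow(ref_center, half_width)
    chosen = _eligible(pairs, tau0, w_tau0, w_ref)
    if not chosen:
        raise CoverageError(f"no longitudinal pairs cover tau0={tau0} months")
    weights = np.array(
        [kernel.weight(p.tau_prime, tau0) * kernel.weight(p.tau, ref_center) for p in chosen]
    )
    weights = weights / weights.sum()
    grid = chosen[0].transported.grid
    acc = np.zeros(grid.shape + (3,))
    for p, w in zip(chosen, weights):
        if p.transported is None:
            raise ValidationError("pair lacks a transported field")
        grid.require_compatible(p.transported.grid)
        acc += w * p.transported.vectors
    return DisplacementField(grid, acc)


def propagate_atlas(
    reference: AtlasBundle,
    phi_tau0: DisplacementField,
    age_months: float | None = None,
) -> AtlasBundle:
    """Warp the reference atlas with a regressed field.

    Volumes are resampled with the pull-back field; surface vertices move
    with the inverse of the field so the warped white surface stays on the
    warped WM/GM interface.
    """
    from .data_model import (
        ConvergenceError,
        invert_displacement_best_effort,
        inversion_residual_at,
    )

    reference.t1w.grid.require_compatible(phi_tau0.grid)
    try:
        psi = invert_displacement(phi_tau0, max_iter=60, tol=1e-3)
    except ConvergenceError:
        # fields assembled from many registrations may fold far from the
        # anatomy; a pseudo-inverse is acceptable as long as it is accurate
        # where the surfaces actually live (checked below)
        psi = invert_displacement_best_effort(phi_tau0)
    surfaces = {}
    tol_mm = 0.5 * float(min(phi_tau0.grid.spacing))
    for hemi, hs in reference.surfaces.items():
        meshes = {}
        for name, mesh in (("white", hs.white), ("pial", hs.pial)):
            resid = inversion_residual_at(phi_tau0, psi, mesh.vertices)
            if resid.mean() > tol_mm:
                raise ConvergenceError(
                    f"inverse deformation inaccurate at {hemi} {name} surface "
                    f"(mean residual {resid.mean():.2f} mm)"
                )
            v = mesh.vertices + sample_vectors(psi.vectors, psi.grid, mesh.vertices)
            meshes[name] = TriangleMesh(v, mesh.triangles.copy())
        surfaces[hemi] = HemiSurfaces(meshes["white"], meshes["pial"])
    return AtlasBundle(
        age_months=float(age_months if age_months is not None else reference.age_months),
        t1w=warp_scalar_volume(reference.t1w, phi_tau0),
        t2w=warp_scalar_volume(reference.t2w, phi_tau0),
        tissue_prob=warp_tissue_map(reference.tissue_prob, phi_tau0),
        tissue_label=warp_label_volume(reference.tissue_label, phi_tau0),
        surfaces=surfaces,
    )


def _inverse_long_map(pair: LongitudinalPair, pts: np.ndarray) -> np.ndarray:
    """Phi_L^{-1} applied to points: tau-frame -> tau'-frame (de-aging).

    With the affine/nonlinear decomposition the affine factor is applied
    analytically; the nonlinear inverse is cached on the pair.
    """
    if pair.long_affine is not None and pair.long_nl is not None:
        inv = getattr(pair, "_inv_long_nl", None)
        if inv is None:
            from .data_model import ConvergenceError, invert_displacement_best_effort

            try:
                inv = invert_displacement(pair.long_nl, max_iter=60, tol=1e-3)
            except ConvergenceError:
                inv = invert_displacement_best_effort(pair.long_nl)
            pair._inv_long_nl = inv
        r = pair.long_affine.apply(pts)
        return r + sample_vectors(inv.vectors, inv.grid, r)
    inv = getattr(pair, "_inv_long", None)
    if inv is None:
        inv = invert_displacement(pair.phi_long, max_iter=60, tol=1e-3)
        pair._inv_long = inv
    return pts + sample_vectors(inv.vectors, inv.grid, pts)


def build_month_intensity_atlas(
    pairs: list[LongitudinalPair],
    tau0: float,
    phi_tau0: DisplacementField,
    kernel: TemporalKernel | None = None,
    ref_center: float = 12.0,
    half_width: float = 1.5,
) -> tuple[ScalarVolume, ScalarVolume]:
    """T1w/T2w atlases at tau0 from the tau' intensity images.

    Each tau0-atlas point x is mapped through the regressed field into the
    reference atlas (Phi_par), then into the subject's tau frame
    (Phi_to_atlas) and back to the tau' visit (Phi_L^{-1}); the tau' image
    is sampled there and the results weighted-averaged.  With the subject's
    own transported field in place of the regressed one this chain
    collapses to the subject-to-atlas map, which is why the regressed field
    must be used.
    """
    kernel = kernel or TemporalKernel()
    w_tau0 = AgeWindow(tau0, half_width)
    w_ref = AgeWindow(ref_center, half_width)
    chosen = [
        p
        for p in _eligible(pairs, tau0, w_tau0, w_ref)
        if p.scan_prime is not None
    ]
    if not chosen:
        raise CoverageError(f"no longitudinal pairs with images cover tau0={tau0}")
    weights = [
        kernel.weight(p.tau_prime, tau0) * kernel.weight(p.tau, ref_center)
        for p in chosen
    ]
    grid = phi_tau0.grid
    x = grid.world_coords().reshape(-1, 3)
    y = x + phi_tau0.vectors.reshape(-1, 3)
    t1s, t2s = [], []
    for p in chosen:
        # atlas point -> subject tau frame
        if p.atlas_affine is not None and p.atlas_nl is not None:
            q = p.atlas_affine.inverse().apply(
                y + sample_vectors(p.atlas_nl.vectors, grid, y)
            )
        else:
            q = y + sample_vectors(p.phi_to_atlas.vectors, grid, y)
        # tau frame -> tau' visit frame (de-aging)
        r = _inverse_long_map(p, q)
        from .data_model import sample_scalar

        t1 = sample_scalar(p.scan_prime.t1w.values, grid, r).reshape(grid.shape)
        t2 = sample_scalar(p.scan_prime.t2w.values, grid, r).reshape(grid.shape)
        t1s.append(ScalarVolume(grid, t1))
        t2s.append(ScalarVolume(grid, t2))
    return fuse_intensity(t1s, weights), fuse_intensity(t2s, weights)


@dataclass
class MonthAtlasResult:
    months: dict  # tau0 -> AtlasBundle
    coverage: dict  # tau0 -> number of pairs used
    skipped: list  # months with zero coverage


def build_all_months(
    pairs: list[LongitudinalPair],
    reference: AtlasBundle,
    months: list[float],
    kernel: TemporalKernel | None = None,
    ref_center: float = 12.0,
    half_width: float = 1.5,
    with_intensity: bool = True,
) -> MonthAtlasResult:
    """Task (ii): propagate the reference atlas to each requested month.

    Pairs must carry transported fields (see :func:`parallel_transport`).
    Months with zero coverage are skipped with a warning and listed in the
    result.
    """
    kernel = kernel or TemporalKernel()
    w_ref = AgeWindow(ref_center, half_width)
    out, coverage, skipped = {}, {}, []
    for tau0 in months:
        eligible = _eligible(pairs, tau0, AgeWindow(tau0, half_width), w_ref)
        if not eligible:
            log.warning("month %.1f: no eligible longitudinal pairs, skipped", tau0)
            skipped.append(tau0)
            continue
        phi = kernel_regress_fields(
            pairs, tau0, kernel, ref_center=ref_center, half_width=half_width
        )
        bundle = propagate_atlas(reference, phi, age_months=tau0)
        if with_intensity:
            try:
                t1, t2 = build_month_intensity_atlas(
                    pairs, tau0, phi, kernel, ref_center, half_width
                )
                bundle.t1w, bundle.t2w = t1, t2
            except CoverageError:
                log.warning("month %.1f: no intensity images; kept warped atlas", tau0)
        out[tau0] = bundle
        coverage[tau0] = len(eligible)
    return MonthAtlasResult(out, coverage, skipped)
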