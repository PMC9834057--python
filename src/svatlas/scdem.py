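"""Surface-constrained dynamic elasticity registration (SC-DEM).

The displacement field between a moving and a fixed tissue probability map
is estimated by integrating a damped wave equation in artificial time:

    d^2 phi / dt^2 = alpha * (vector_laplacian(phi) + grad(div(phi)))
                     + beta * f_vol + gamma * f_surf

driven by a volumetric force (the tissue segmentation mismatch times the
warped-map gradient) and a surface force (Gaussian splatting of the
residual between predetermined surface displacements and the current field,
sampled at surface vertices).  Registration halts when the mean combined
force magnitude is negligibly small.

Sign convention: the volumetric mismatch force ``[I_mov(x+phi) - I_ref(x)]
* grad I_mov(x+phi)`` is the *ascent* direction of the squared mismatch
under the pull-back warping convention used throughout this package
(``out(x) = in(x + phi(x))``), so the integrator applies it with a negative
sign; likewise the surface residual is anchored at the *target*
(correspondence) locations by the pair-registration orchestration.
:func:`volumetric_force` itself computes the mismatch force literally, and
is oracle-tested as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.sparse import coo_matrix

from .data_model import (
    AffineTransform,
    DisplacementField,
    TissueProbMap,
    ValidationError,
    VoxelGrid,
    apply_affine_to_tissue_map,
    sample_vectors,
)
from .subjects import SubjectScan

__all__ = [
    "ScdemParams",
    "DivergenceError",
    "affine_align",
    "volumetric_force",
    "SurfaceConstraint",
    "surface_force",
    "solve_scdem",
    "register_pair",
    "SolveReport",
]

log = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScdemParams:
    """Parameters of the dynamic-elasticity solver.

    alpha (smoothness), beta (volumetric force weight) and gamma (surface
    force weight) balance the terms of the wave equation; dt is the
    artificial-time integration step (``None`` selects half the CFL limit
    for the grid at solve time).
    """

    alpha: float = 0.15
    beta: float = 8.0
    gamma: float = 1.0
    dt: float | None = None
    damping: float = 0.25
    max_steps: int = 150
    force_tol: float = 1e-4
    surface_kernel_mm: float | None = None  # default: 2 * max spacing

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValidationError("alpha, beta, gamma must be >= 0")
        if not (0.0 <= self.damping < 1.0):
            raise ValidationError("damping must be in [0, 1)")
        if self.dt is not None and self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.force_tol < 0:
            raise ValidationError("force_tol must be >= 0")

    def cfl_limit(self, spacing) -> float:
        """Largest stable dt for the explicit elasticity operator."""
        s = np.asarray(spacing, dtype=float)
        if self.alpha == 0:
            return np.inf
        return float(np.sqrt(1.0 / (self.alpha * 2.0 * (1.0 / s**2).sum())))

    def resolve_dt(self, spacing) -> float:
        lim = self.cfl_limit(spacing)
        if self.dt is None:
            return 0.5 * lim if np.isfinite(lim) else 1.0
        if self.dt >= lim:
            raise ValidationError(
                f"dt={self.dt} violates the stability bound {lim:.4g} "
                f"(dt^2 * alpha * 2*sum(1/spacing^2) must be < 1)"
            )
        return self.dt

    def resolve_kernel(self, spacing) -> float:
        if self.surface_kernel_mm is not None:
            if self.surface_kernel_mm <= 0:
                raise ValidationError("surface_kernel_mm must be > 0")
            return self.surface_kernel_mm
        return 2.0 * float(max(spacing))

    @classmethod
    def for_grid(cls, grid: VoxelGrid, **kwargs) -> "ScdemParams":
        """Construct with dt fixed at half the CFL limit of `grid` (validated)."""
        p = cls(**kwargs)
        return replace(p, dt=p.resolve_dt(grid.spacing))


# --------------------------------------------------------------------------
# affine pre-alignment
# --------------------------------------------------------------------------


def _moments(tmap: TissueProbMap) -> tuple[float, np.ndarray, np.ndarray]:
    w = tmap.channels.sum(axis=-1).ravel()
    total = w.sum()
    if total <= 0:
        raise ValidationError("empty foreground in tissue map")
    x = tmap.grid.world_coords().reshape(-1, 3)
    mu = (w[:, None] * x).sum(axis=0) / total
    d = x - mu
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / total
    return total, mu, cov


def _rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(r)
    if angle < 1e-12:
        return np.eye(3)
    k = r / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def affine_align(
    moving: TissueProbMap, fixed: TissueProbMap, refine_iters: int = 40
) -> AffineTransform:
    """9-dof affine (translation + rotation + anisotropic scale) moving -> fixed.

    Initialized from foreground centroids and second moments of the summed
    tissue probability, then refined by a deterministic local minimization of
    the channelwise SSD of the resampled map.
    """
    _, mu_m, cov_m = _moments(moving)
    _, mu_f, cov_f = _moments(fixed)
    # principal-axis scale initialization (assumes near-aligned orientations)
    s0 = np.sqrt(np.diag(cov_f) / np.diag(cov_m))

    def build(p):
        rot = _rotvec_to_matrix(p[0:3])
        M = rot @ np.diag(np.exp(p[3:6]))
        t = mu_f + p[6:9] - M @ mu_m
        return AffineTransform(M, t)

    # SSD evaluated on a stride-2 lattice of the fixed grid (4x cheaper)
    g = fixed.grid
    coarse = VoxelGrid(
        tuple((n + 1) // 2 for n in g.shape),
        tuple(2 * s for s in g.spacing),
        g.origin,
    )
    fixed_coarse = fixed.channels[::2, ::2, ::2]

    def ssd(p):
        aff = build(p)
        res = apply_affine_to_tissue_map(moving, aff, coarse)
        return float(((res.channels - fixed_coarse) ** 2).sum())

    p0 = np.concatenate([np.zeros(3), np.log(s0), np.zeros(3)])
    if refine_iters > 0:
        res = optimize.minimize(
            ssd,
            p0,
            method="Powell",
            options={"maxiter": refine_iters, "maxfev": 400, "xtol": 1e-4, "ftol": 1e-8},
        )
        p = res.x
    else:
        p = p0
    return build(p)


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------


def volumetric_force(moving_warped: TissueProbMap, fixed: TissueProbMap) -> np.ndarray:
    """Tissue-mismatch force, summed over (WM, GM, CSF) channels.

    f(x) = sum_c [I_mov,c(x+phi) - I_ref,c(x)] * grad I_mov,c(x+phi)
    with gradients by central differences on the warped moving map (1/mm).
    Returns an (X, Y, Z, 3) array.
    """
    moving_warped.grid.require_compatible(fixed.grid)
    sp = moving_warped.grid.spacing
    f = np.zeros(moving_warped.grid.shape + (3,))
    for c in range(3):
        resid = moving_warped.channels[..., c] - fixed.channels[..., c]
        g = np.gradient(moving_warped.channels[..., c], *sp, edge_order=1)
        for ax in range(3):
            f[..., ax] += resid * g[ax]
    return f


@dataclass
class SurfaceConstraint:
    """Predetermined displacement targets anchored at world-space points."""

    points: np.ndarray  # (V, 3) mm, in the fixed image's world frame
    target_disp: np.ndarray  # (V, 3) mm

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.target_disp = np.asarray(self.target_disp, dtype=float)
        if self.points.shape != self.target_disp.shape or self.points.shape[1] != 3:
            raise ValidationError("points/target_disp must both be (V, 3)")
        if not (np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.target_disp))):
            raise ValidationError("non-finite surface constraint")


class _Splatter:
    """Precomputed Gaussian splat operator from vertices to the voxel grid.

    The kernel is truncated at 3*kernel_mm; voxels farther than that from
    every vertex receive exactly zero.
    """

    def __init__(self, grid: VoxelGrid, points: np.ndarray, kernel_mm: float):
        self.grid = grid
        radius = 3.0 * kernel_mm
        sp = grid.spacing_arr
        half = np.ceil(radius / sp).astype(int)
        offs = np.stack(
            np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        base = np.floor(grid.world_to_index(points) + 0.5).astype(int)  # nearest voxel
        vox = base[:, None, :] + offs[None, :, :]  # (V, K, 3)
        inb = np.all((vox >= 0) & (vox < np.asarray(grid.shape)), axis=-1)
        centers = grid.origin_arr + vox * sp
        d2 = ((centers - points[:, None, :]) ** 2).sum(axis=-1)
        w = np.exp(-d2 / (2.0 * kernel_mm**2))
        keep = inb & (d2 <= radius**2)
        v_idx, k_idx = np.nonzero(keep)
        flat = np.ravel_multi_index(tuple(vox[v_idx, k_idx].T), grid.shape)
        n_vox = int(np.prod(grid.shape))
        self.W = coo_matrix(
            (w[v_idx, k_idx], (flat, v_idx)), shape=(n_vox, len(points))
        ).tocsr()
        self.wsum = np.asarray(self.W.sum(axis=1)).ravel()
        self.nonzero = self.wsum > 0

    def splat(self, values: np.ndarray) -> np.ndarray:
        """Weight-saturated splat of per-vertex vectors on the grid."""
        num = self.W @ values
        out = num / np.maximum(self.wsum, 1.0)[:, None]
        out[~self.nonzero] = 0.0
        return out.reshape(self.grid.shape + (values.shape[1],))


def surface_force(
    constraints: list[SurfaceConstraint],
    current_field: DisplacementField,
    kernel_mm: float,
    splatters: list[_Splatter] | None = None,
) -> np.ndarray:
    """Gaussian-splatted residual between target and current displacements.

    For each constraint vertex v the residual r(v) = target(v) -
    phi_current(v) (field sampled trilinearly at the vertex); residuals are
    splatted with a Gaussian of width kernel_mm, normalized by the splatted
    weight sum (saturated at the single-vertex peak weight, so the force
    decays with the Gaussian profile away from sparse vertices instead of
    holding full strength throughout the support), and truncated at
    3*kernel_mm.
    """
    grid = current_field.grid
    if not constraints:
        log.warning("surface_force called with no constraints; returning zero field")
        return np.zeros(grid.shape + (3,))
    if splatters is None:
        splatters = [_Splatter(grid, c.points, kernel_mm) for c in constraints]
    total = np.zeros(grid.shape + (3,))
    wtot = np.zeros(grid.shape)
    for c, sp in zip(constraints, splatters):
        phi_at = sample_vectors(current_field.vectors, grid, c.points)
        resid = c.target_disp - phi_at
        num = (sp.W @ resid).reshape(grid.shape + (3,))
        total += num
        wtot += sp.wsum.reshape(grid.shape)
    total /= np.maximum(wtot, 1.0)[..., None]
    total[wtot == 0] = 0.0
    return total


# --------------------------------------------------------------------------
# the wave-equation solver
# --------------------------------------------------------------------------


try:
    import numba as _numba

    @_numba.njit(cache=False, fastmath=True)
    def _force_kernel(warped, fixed, inv_2h, out):  # pragma: no cover - jitted
        """Literal tissue-mismatch force (resid * central-diff gradient of
        the warped map, summed over channels); equals volumetric_force."""
        nx, ny, nz, nc = warped.shape
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            fx = inv_2h[0] if 0 < i < nx - 1 else 2.0 * inv_2h[0]
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                fy = inv_2h[1] if 0 < j < ny - 1 else 2.0 * inv_2h[1]
                for k in range(nz):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < nz - 1 else nz - 1
                    fz = inv_2h[2] if 0 < k < nz - 1 else 2.0 * inv_2h[2]
                    ax = ay = az = 0.0
                    for c in range(nc):
                        resid = warped[i, j, k, c] - fixed[i, j, k, c]
                        ax += resid * (warped[ip, j, k, c] - warped[im, j, k, c]) * fx
                        ay += resid * (warped[i, jp, k, c] - warped[i, jm, k, c]) * fy
                        az += resid * (warped[i, j, kp, c] - warped[i, j, km, c]) * fz
                    out[i, j, k, 0] = ax
                    out[i, j, k, 1] = ay
                    out[i, j, k, 2] = az

    @_numba.njit(cache=False, fastmath=True)
    def _elastic_kernel(phi, inv_h2, out):  # pragma: no cover - jitted
        """alpha-free elastic operator: vector Laplacian + grad(div),
        replicate boundaries, second-order central differences."""
        nx, ny, nz, _ = phi.shape
        hx2, hy2, hz2 = inv_h2[0], inv_h2[1], inv_h2[2]
        hx = np.sqrt(hx2)
        hy = np.sqrt(hy2)
        hz = np.sqrt(hz2)
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                for k in range(nz):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < nz - 1 else nz - 1
                    for c in range(3):
                        out[i, j, k, c] = (
                            (phi[ip, j, k, c] - 2 * phi[i, j, k, c] + phi[im, j, k, c]) * hx2
                            + (phi[i, jp, k, c] - 2 * phi[i, j, k, c] + phi[i, jm, k, c]) * hy2
                            + (phi[i, j, kp, c] - 2 * phi[i, j, k, c] + phi[i, j, km, c]) * hz2
                        )
        # grad(div): central differences of the divergence field
        div = np.empty((nx, ny, nz))
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            di = (ip - im) if ip != im else 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                dj = (jp - jm) if jp != jm else 1
                for k in range(nz):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < nz - 1 else nz - 1
                    dk = (kp - km) if kp != km else 1
                    div[i, j, k] = (
                        (phi[ip, j, k, 0] - phi[im, j, k, 0]) / di * hx
                        + (phi[i, jp, k, 1] - phi[i, jm, k, 1]) / dj * hy
                        + (phi[i, j, kp, 2] - phi[i, j, km, 2]) / dk * hz
                    )
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            di = (ip - im) if ip != im else 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                dj = (jp - jm) if jp != jm else 1
                for k in range(nz):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < nz - 1 else nz - 1
                    dk = (kp - km) if kp != km else 1
                    out[i, j, k, 0] += (div[ip, j, k] - div[im, j, k]) / di * hx
                    out[i, j, k, 1] += (div[i, jp, k] - div[i, jm, k]) / dj * hy
                    out[i, j, k, 2] += (div[i, j, kp] - div[i, j, km]) / dk * hz

except ImportError:  # pragma: no cover
    _numba = None


def _elastic_operator(phi: np.ndarray, spacing) -> np.ndarray:
    """Vector Laplacian + grad(div) with replicate boundaries (1/mm^2)."""
    if _numba is not None:
        out = np.empty_like(phi)
        inv_h2 = np.asarray([1.0 / s**2 for s in spacing])
        _elastic_kernel(phi, inv_h2, out)
        return out
    return _vector_laplacian(phi, spacing) + _grad_div(phi, spacing)


def _vector_laplacian(vec: np.ndarray, spacing) -> np.ndarray:
    """Componentwise Laplacian, replicate (Neumann) boundaries, mm units."""
    out = np.zeros_like(vec)
    for ax in range(3):
        h2 = spacing[ax] ** 2
        mid = [slice(None)] * 4
        hi = [slice(None)] * 4
        lo = [slice(None)] * 4
        mid[ax], hi[ax], lo[ax] = slice(1, -1), slice(2, None), slice(None, -2)
        out[tuple(mid)] += (vec[tuple(hi)] - 2.0 * vec[tuple(mid)] + vec[tuple(lo)]) / h2
        # replicate boundary: second difference collapses to a first difference
        first = [slice(None)] * 4
        second = [slice(None)] * 4
        first[ax], second[ax] = slice(0, 1), slice(1, 2)
        out[tuple(first)] += (vec[tuple(second)] - vec[tuple(first)]) / h2
        last = [slice(None)] * 4
        prev = [slice(None)] * 4
        last[ax], prev[ax] = slice(-1, None), slice(-2, -1)
        out[tuple(last)] += (vec[tuple(prev)] - vec[tuple(last)]) / h2
    return out


def _grad_div(vec: np.ndarray, spacing) -> np.ndarray:
    div = np.zeros(vec.shape[:3])
    for ax in range(3):
        div += np.gradient(vec[..., ax], spacing[ax], axis=ax, edge_order=1)
    out = np.empty_like(vec)
    for ax in range(3):
        out[..., ax] = np.gradient(div, spacing[ax], axis=ax, edge_order=1)
    return out


@dataclass
class SolveReport:
    steps: int
    converged: bool
    final_mean_force: float
    reason: str


def _warp_channels(channels: np.ndarray, grid: VoxelGrid, phi: np.ndarray, coords) -> np.ndarray:
    from .data_model import trilinear_channels

    return np.clip(trilinear_channels(channels, grid, coords + phi), 0.0, 1.0)


def solve_scdem(
    moving: TissueProbMap,
    fixed: TissueProbMap,
    surface_constraints: list[SurfaceConstraint] | None = None,
    params: ScdemParams | None = None,
    phi0: np.ndarray | None = None,
    return_report: bool = False,
):
    """Estimate the displacement field moving -> fixed by damped leapfrog
    integration of the dynamic-elasticity equation.

    Affine pre-alignment is assumed to have been applied.  `phi0` is a test
    hook for a nonzero initial field.  Returns the DisplacementField (and a
    SolveReport when requested).
    """
    moving.grid.require_compatible(fixed.grid)
    params = params or ScdemParams()
    grid = fixed.grid
    sp = grid.spacing
    dt = params.resolve_dt(sp)
    if params.dt is None and params.beta > 0:
        # auto-dt must also respect the stiffness of the mismatch force
        # (locally f ~ -k*phi with k ~ beta * |grad I|^2)
        g2max = 0.0
        for c in range(3):
            gc = np.gradient(moving.channels[..., c], *sp, edge_order=1)
            g2max += max(float(np.abs(a).max()) for a in gc) ** 2
        if g2max > 0:
            dt = min(dt, 0.7 / np.sqrt(params.beta * g2max))
    kernel = params.resolve_kernel(sp)

    constraints = surface_constraints or []
    splatters = [_Splatter(grid, c.points, kernel) for c in constraints]

    coords = grid.world_coords()
    phi = np.zeros(grid.shape + (3,)) if phi0 is None else np.array(phi0, dtype=float)
    vel = np.zeros_like(phi)
    extent = grid.extent_mm.max()
    fixed_chans = np.ascontiguousarray(fixed.channels)
    inv_2h = np.asarray([1.0 / (2.0 * s) for s in sp])

    report = SolveReport(0, False, np.inf, "max_steps")
    use_surface = params.gamma > 0 and constraints
    for step in range(1, params.max_steps + 1):
        force = np.zeros_like(phi)
        if params.beta > 0:
            warped = _warp_channels(moving.channels, moving.grid, phi, coords)
            # descent direction of the mismatch (see module docstring on sign)
            if _numba is not None:
                fv = np.empty_like(phi)
                _force_kernel(warped, fixed_chans, inv_2h, fv)
                force -= params.beta * fv
            else:
                warped_map = TissueProbMap.__new__(TissueProbMap)
                warped_map.grid = grid
                warped_map.channels = warped
                force -= params.beta * volumetric_force(warped_map, fixed)
        if use_surface:
            force += params.gamma * surface_force(
                constraints, DisplacementField(grid, phi), kernel, splatters
            )
        mean_force = float(np.linalg.norm(force, axis=-1).mean())
        if mean_force < params.force_tol:
            report = SolveReport(step, True, mean_force, "force_tol")
            break
        accel = force
        if params.alpha > 0:
            accel = accel + params.alpha * _elastic_operator(phi, sp)
        vel = (1.0 - params.damping) * (vel + dt * accel)
        phi = phi + dt * vel
        if step % 10 == 0 or step == params.max_steps:
            if not np.all(np.isfinite(phi)):
                raise DivergenceError(f"non-finite displacement at step {step}")
            if np.abs(phi).max() > extent:
                raise DivergenceError(
                    f"displacement exceeded grid extent at step {step}"
                )
        report = SolveReport(step, False, mean_force, "max_steps")

    field = DisplacementField(grid, phi)
    log.info(
        "scdem: %d steps, mean force %.3e (%s)",
        report.steps,
        report.final_mean_force,
        report.reason,
    )
    if return_report:
        return field, report
    return field


# --------------------------------------------------------------------------
# full pair registration
# --------------------------------------------------------------------------


def register_pair(
    moving: SubjectScan,
    fixed: SubjectScan,
    params: ScdemParams | None = None,
    use_surfaces: bool = True,
    precomputed_warps: dict | None = None,
) -> tuple[AffineTransform, DisplacementField]:
    """Affine + SC-DEM registration of one scan pair.

    Runs affine pre-alignment on the tissue maps, derives surface-constraint
    displacements from spherical surface registration (or precomputed warps)
    when both scans carry surfaces, then solves the wave equation.  The
    returned displacement is the pull-back field on the fixed grid; the
    total resampling map is the affine applied after the field
    (out(x) = moving(affine^{-1}(x + phi(x)))).
    """
    from .sphere_reg import propagate_to_anatomical, register_spherical_maps
    from .surface import TriangleMesh, inflate_surface, map_to_sphere, mean_curvature

    params = params or ScdemParams()
    affine = affine_align(moving.tissue, fixed.tissue)
    moved = apply_affine_to_tissue_map(moving.tissue, affine, fixed.tissue.grid)

    constraints: list[SurfaceConstraint] = []
    if use_surfaces and params.gamma > 0 and moving.surfaces and fixed.surfaces:
        for hemi in sorted(set(moving.surfaces) & set(fixed.surfaces)):
            mov_h, fix_h = moving.surfaces[hemi], fixed.surfaces[hemi]
            # moving surfaces mapped into the fixed frame by the affine
            mov_white = TriangleMesh(
                affine.apply(mov_h.white.vertices), mov_h.white.triangles
            )
            mov_pial = TriangleMesh(
                affine.apply(mov_h.pial.vertices), mov_h.pial.triangles
            )
            if precomputed_warps and hemi in precomputed_warps:
                warp, fix_sphere = precomputed_warps[hemi]
            else:
                mov_sphere = spherical_map_of(mov_white)
                fix_sphere = spherical_map_of(fix_h.white)
                warp = register_spherical_maps(mov_sphere, fix_sphere)
            dw, dp = propagate_to_anatomical(
                warp, mov_white, mov_pial, fix_h.white, fix_h.pial, fix_sphere
            )
            # anchor the constraint at the corresponding fixed-surface points
            # with the displacement pointing back to the moving surface, so a
            # converged pull-back field resamples moving tissue onto the
            # fixed surfaces
            for mov_mesh, d in ((mov_white, dw), (mov_pial, dp)):
                constraints.append(
                    SurfaceConstraint(points=mov_mesh.vertices + d, target_disp=-d)
                )
    phi = solve_scdem(moved, fixed.tissue, constraints, params)
    return affine, phi


def spherical_map_of(
    white: TriangleMesh, n_inflate: int = 120, smooth_weight: float = 0.5
):
    """Inflate a white surface and map it to the unit sphere with attributes."""
    from .surface import inflate_surface, map_to_sphere, mean_curvature

    curv = mean_curvature(white)
    inflated, conv = inflate_surface(white, n_steps=n_inflate, smooth_weight=smooth_weight)
    inflated.attributes["convexity_mm"] = conv
    inflated.attributes["mean_curvature_per_mm"] = curv
    smap = map_to_sphere(inflated)
    smap.convexity = conv
    smap.curvature = curv
    return smap
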