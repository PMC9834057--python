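"""Cortical surface processing.

Inflation with average-convexity accumulation, spherical mapping by metric
distortion minimization, curvature / area / thickness measures and
T1w/T2w ribbon sampling.

Sign conventions: average convexity is negative in sulci and positive on
gyral crowns (a sulcal fundus moves outward while the surface inflates, and
the accumulated outward motion is negated); mean curvature is positive on
convex (gyral) regions, so a sphere of radius r has H = +1/r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree

from .data_model import ScalarVolume, ValidationError, sample_scalar

__all__ = [
    "TriangleMesh",
    "SphericalMap",
    "TopologyError",
    "MappingError",
    "inflate_surface",
    "map_to_sphere",
    "mean_curvature",
    "surface_area",
    "vertex_areas",
    "cortical_thickness",
    "sample_ribbon_ratio",
    "resample_attribute_on_sphere",
    "locate_on_sphere",
    "vertex_normals",
]

log = logging.getLogger(__name__)


class TopologyError(ValueError):
    """Mesh violates the closed genus-0 requirement."""


class MappingError(RuntimeError):
    """Spherical mapping could not remove folded triangles."""


@dataclass
class TriangleMesh:
    """Closed, consistently oriented triangle mesh with per-vertex attributes."""

    vertices: np.ndarray  # (N, 3) mm
    triangles: np.ndarray  # (M, 3) int
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValidationError("triangles must be (M, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValidationError("triangle index out of range")

    # -- structural checks --------------------------------------------------
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = len(np.unique(edges, axis=0))
        return len(self.vertices) - n_edges + len(self.triangles)

    def validate_genus0(self) -> None:
        edges = np.sort(self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise TopologyError("mesh is not closed/edge-manifold")
        chi = len(self.vertices) - len(uniq) + len(self.triangles)
        if chi != 2:
            raise TopologyError(f"Euler characteristic {chi} != 2 (genus > 0)")
        referenced = np.zeros(len(self.vertices), dtype=bool)
        referenced[self.triangles.ravel()] = True
        if not referenced.all():
            raise TopologyError("mesh has unreferenced vertices")

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            {k: v.copy() for k, v in self.attributes.items()},
        )


@dataclass
class SphericalMap:
    """Unit-sphere embedding of a hemisphere mesh with folding attributes."""

    positions: np.ndarray  # (N, 3) unit vectors
    triangles: np.ndarray
    convexity: np.ndarray | None = None  # mm
    curvature: np.ndarray | None = None  # 1/mm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        norms = np.linalg.norm(self.positions, axis=1)
        if np.abs(norms - 1.0).max() > 1e-6:
            raise ValidationError("spherical positions must be unit vectors")
        self.triangles = np.asarray(self.triangles, dtype=int)


# --------------------------------------------------------------------------
# basic differential quantities
# --------------------------------------------------------------------------


def _triangle_areas_normals(verts, tris):
    p0, p1, p2 = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    cr = np.cross(p1 - p0, p2 - p0)
    nrm = np.linalg.norm(cr, axis=1)
    areas = 0.5 * nrm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = np.where(nrm[:, None] > 0, cr / np.where(nrm == 0, 1, nrm)[:, None], 0)
    return areas, normals


def surface_area(mesh: TriangleMesh) -> float:
    areas, _ = _triangle_areas_normals(mesh.vertices, mesh.triangles)
    return float(areas.sum())


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """One third of incident triangle area per vertex (partition of total area)."""
    areas, _ = _triangle_areas_normals(mesh.vertices, mesh.triangles)
    va = np.zeros(len(mesh.vertices))
    np.add.at(va, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    return va


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted outward vertex normals (unit)."""
    areas, tnorm = _triangle_areas_normals(mesh.vertices, mesh.triangles)
    vn = np.zeros_like(mesh.vertices)
    w = tnorm * areas[:, None]
    for k in range(3):
        np.add.at(vn, mesh.triangles[:, k], w)
    n = np.linalg.norm(vn, axis=1, keepdims=True)
    return vn / np.where(n == 0, 1, n)


def _adjacency(mesh: TriangleMesh):
    """Uniform (umbrella) adjacency as a row-normalized sparse matrix."""
    tris = mesh.triangles
    i = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 1], tris[:, 2], tris[:, 2], tris[:, 0]])
    j = np.concatenate([tris[:, 1], tris[:, 0], tris[:, 2], tris[:, 1], tris[:, 0], tris[:, 2]])
    pairs = np.unique(np.stack([i, j], axis=1), axis=0)
    n = len(mesh.vertices)
    data = np.ones(len(pairs))
    A = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    from scipy.sparse import diags

    return diags(1.0 / np.where(deg == 0, 1, deg)) @ A


def mean_curvature(mesh: TriangleMesh) -> np.ndarray:
    """Discrete mean curvature via the cotangent Laplace-Beltrami operator.

    H(v) = |Laplacian(v)| / 2 with the sign taken positive where the
    Laplacian points inward (convex/gyral regions).  Units 1/mm.
    """
    verts, tris = mesh.vertices, mesh.triangles
    areas, _ = _triangle_areas_normals(verts, tris)
    if np.any(areas <= 1e-12):
        raise ValidationError("degenerate (zero-area) triangles present")

    n = len(verts)
    lap = np.zeros_like(verts)
    wsum = np.zeros(n)
    # cotangent weights: for each triangle corner, the opposite edge gets cot(angle)
    for corner in range(3):
        a = tris[:, corner]
        b = tris[:, (corner + 1) % 3]
        c = tris[:, (corner + 2) % 3]
        u = verts[b] - verts[a]
        v = verts[c] - verts[a]
        cot = (u * v).sum(axis=1) / np.linalg.norm(np.cross(u, v), axis=1)
        # edge (b, c) accumulates cot at 'a'
        for p, q in ((b, c), (c, b)):
            np.add.at(lap, p, 0.5 * cot[:, None] * (verts[q] - verts[p]))
            np.add.at(wsum, p, 0.5 * cot)

    # mixed (here: barycentric third) vertex areas
    va = vertex_areas(mesh)
    lap = lap / np.where(va == 0, 1, va)[:, None]
    normals = vertex_normals(mesh)
    mag = np.linalg.norm(lap, axis=1) / 2.0
    sign = -np.sign((lap * normals).sum(axis=1))
    sign[sign == 0] = 1.0
    return sign * mag


def cortical_thickness(white: TriangleMesh, pial: TriangleMesh) -> np.ndarray:
    """Euclidean distance between corresponding white and pial vertices (mm)."""
    if len(white.vertices) != len(pial.vertices):
        raise ValidationError(
            "white and pial surfaces must share vertex count/correspondence"
        )
    return np.linalg.norm(pial.vertices - white.vertices, axis=1)


# --------------------------------------------------------------------------
# inflation with convexity accumulation
# --------------------------------------------------------------------------


def inflate_surface(
    white: TriangleMesh, n_steps: int = 200, smooth_weight: float = 0.5
) -> tuple[TriangleMesh, np.ndarray]:
    """Inflate a white surface, accumulating average convexity.

    Each step applies umbrella smoothing with the displacement normalized by
    the local mean squared edge length (so that a round sphere is a fixed
    point of the flow and accrues no spurious convexity at irregular-valence
    vertices), followed by a global rescaling about the centroid that
    restores the total surface area.  The convexity of a vertex is the
    negated accumulated displacement along its outward normal over all steps
    (mm): sulcal fundi travel outward during inflation and therefore end
    negative, gyral crowns positive.  The area-weighted mean increment is
    removed each step so that convexity integrates to ~0 over the surface.
    """
    white.validate_genus0()
    A = _adjacency(white)
    target_area = surface_area(white)
    verts = white.vertices.copy()
    convexity = np.zeros(len(verts))
    mesh = TriangleMesh(verts, white.triangles)
    for _ in range(n_steps):
        normals = vertex_normals(mesh)
        va = vertex_areas(mesh)
        # mean squared edge length per vertex, used to equalize step sizes
        nb_sq = (
            A @ (verts**2).sum(axis=1)
            - 2.0 * (verts * (A @ verts)).sum(axis=1)
            + (verts**2).sum(axis=1)
        )
        corr = nb_sq.mean() / np.maximum(nb_sq, 1e-30)
        smoothed = verts + smooth_weight * corr[:, None] * (A @ verts - verts)
        centroid = smoothed.mean(axis=0)
        m2 = TriangleMesh(smoothed, white.triangles)
        scale = np.sqrt(target_area / surface_area(m2))
        new = centroid + (smoothed - centroid) * scale
        step_disp = ((new - verts) * normals).sum(axis=1)
        step_disp -= np.average(step_disp, weights=va)
        convexity -= step_disp
        verts = new
        mesh = TriangleMesh(verts, white.triangles)
    mesh.attributes["convexity_mm"] = convexity
    return mesh, convexity


# --------------------------------------------------------------------------
# spherical mapping by metric-distortion minimization
# --------------------------------------------------------------------------


def _edges_of(tris: np.ndarray) -> np.ndarray:
    e = np.sort(tris[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    return np.unique(e, axis=0)


def _spherical_orient(pos: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Signed orientation of spherical triangles (positive = outward CCW)."""
    p0, p1, p2 = pos[tris[:, 0]], pos[tris[:, 1]], pos[tris[:, 2]]
    return np.einsum("ij,ij->i", np.cross(p0, p1), p2)


def map_to_sphere(
    inflated: TriangleMesh,
    reference: TriangleMesh | None = None,
    max_iter: int = 500,
    step: float = 0.1,
    rel_tol: float = 1e-5,
) -> SphericalMap:
    """Project an inflated surface to the unit sphere and minimize metric distortion.

    The distortion energy is the sum of squared differences between spherical
    edge lengths and the (scale-normalized) edge lengths of `reference`
    (default: the inflated mesh itself, which for near-spherical input gives
    near-identity mapping).  Gradient steps that would fold a spherical
    triangle are rejected for the offending vertices.
    """
    tris = inflated.triangles
    centroid = inflated.vertices.mean(axis=0)
    pos = inflated.vertices - centroid
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)

    ref = reference if reference is not None else inflated
    edges = _edges_of(tris)
    ref_len = np.linalg.norm(ref.vertices[edges[:, 0]] - ref.vertices[edges[:, 1]], axis=1)
    # normalize reference metric to unit-sphere scale
    ref_len = ref_len * np.sqrt(4.0 * np.pi / surface_area(ref))

    orient0 = _spherical_orient(pos, tris)
    if np.any(orient0 <= 0):
        # initial radial projection should be valid for near-convex input
        raise MappingError(
            f"{int((orient0 <= 0).sum())} folded triangles after radial projection"
        )

    def energy(p):
        el = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
        return float(((el - ref_len) ** 2).sum())

    n = len(pos)
    e_prev = energy(pos)
    e_proj = e_prev
    for _ in range(max_iter):
        d = pos[edges[:, 0]] - pos[edges[:, 1]]
        el = np.linalg.norm(d, axis=1)
        coef = 2.0 * (el - ref_len) / np.where(el == 0, 1, el)
        grad = np.zeros_like(pos)
        np.add.at(grad, edges[:, 0], coef[:, None] * d)
        np.add.at(grad, edges[:, 1], -coef[:, None] * d)
        # tangential component only
        grad -= (grad * pos).sum(axis=1, keepdims=True) * pos
        trial = pos - step * grad
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        # reject vertices whose motion folds a triangle
        for _half in range(10):
            bad_tris = _spherical_orient(trial, tris) <= 0
            if not bad_tris.any():
                break
            bad_verts = np.unique(tris[bad_tris])
            trial[bad_verts] = 0.5 * (trial[bad_verts] + pos[bad_verts])
            trial[bad_verts] /= np.linalg.norm(trial[bad_verts], axis=1, keepdims=True)
        else:
            trial[bad_verts] = pos[bad_verts]
        e_new = energy(trial)
        if e_new >= e_prev:
            step *= 0.5
            if step < 1e-6:
                break
            continue
        pos = trial
        if (e_prev - e_new) / max(e_prev, 1e-300) < rel_tol:
            e_prev = e_new
            break
        e_prev = e_new

    bad = np.flatnonzero(_spherical_orient(pos, tris) <= 0)
    if bad.size:
        raise MappingError(f"folded spherical triangles remain: {bad.tolist()[:20]}")
    if e_prev > e_proj + 1e-12:
        raise MappingError("relaxation increased distortion energy")  # cannot happen
    conv = inflated.attributes.get("convexity_mm")
    curv = inflated.attributes.get("mean_curvature_per_mm")
    return SphericalMap(pos, tris.copy(), convexity=conv, curvature=curv)


# --------------------------------------------------------------------------
# spherical barycentric resampling
# --------------------------------------------------------------------------


def locate_on_sphere(
    positions: np.ndarray, triangles: np.ndarray, targets: np.ndarray, k: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Locate unit-vector targets in a spherical triangulation.

    Returns (triangle index, barycentric coordinates) per target using
    central (gnomonic) barycentric coordinates.  Targets that cannot be
    located exactly fall back to the best candidate triangle (logged).
    """
    targets = np.asarray(targets, dtype=float)
    centroids = positions[triangles].mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    tree = cKDTree(centroids)
    k = min(k, len(triangles))
    _, cand = tree.query(targets, k=k)
    if k == 1:
        cand = cand[:, None]

    tri_pts = positions[triangles]  # (M, 3, 3)
    n_t = len(targets)
    found = np.zeros(n_t, dtype=bool)
    out_tri = np.zeros(n_t, dtype=int)
    out_bc = np.full((n_t, 3), 1.0 / 3.0)
    best_score = np.full(n_t, -np.inf)
    for col in range(cand.shape[1]):
        tri_idx = cand[:, col]
        mats = tri_pts[tri_idx].transpose(0, 2, 1)  # columns = corner vectors
        det_ok = np.abs(np.linalg.det(mats)) > 1e-12
        bc = np.full((n_t, 3), -np.inf)
        if det_ok.any():
            bc[det_ok] = np.linalg.solve(mats[det_ok], targets[det_ok][..., None])[..., 0]
        s = bc.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            bc = np.where(np.abs(s) > 1e-12, bc / s, -np.inf)
        score = np.where(det_ok, bc.min(axis=1), -np.inf)
        inside = (score >= -1e-9) & ~found
        out_tri[inside] = tri_idx[inside]
        out_bc[inside] = np.clip(bc[inside], 0.0, None)
        found[inside] = True
        # track the best fallback candidate for never-located targets
        improve = ~found & (score > best_score) & np.isfinite(score)
        if improve.any():
            out_bc[improve] = np.clip(bc[improve], 0.0, None)
            out_tri[improve] = tri_idx[improve]
            best_score[improve] = score[improve]

    if not found.all():
        log.debug("spherical location fell back for %d targets", int((~found).sum()))
    out_bc /= out_bc.sum(axis=1, keepdims=True)
    return out_tri, out_bc


def resample_attribute_on_sphere(
    source: SphericalMap, values: np.ndarray, target_positions: np.ndarray
) -> np.ndarray:
    """Barycentric interpolation of per-vertex values at target unit vectors."""
    values = np.asarray(values, dtype=float)
    tri, bc = locate_on_sphere(source.positions, source.triangles, target_positions)
    corner_vals = values[source.triangles[tri]]  # (N, 3[, C])
    if corner_vals.ndim == 2:
        return (corner_vals * bc).sum(axis=1)
    return (corner_vals * bc[..., None]).sum(axis=1)


# --------------------------------------------------------------------------
# ribbon sampling
# --------------------------------------------------------------------------


def sample_ribbon_ratio(
    t1w: ScalarVolume,
    t2w: ScalarVolume,
    white: TriangleMesh,
    pial: TriangleMesh,
    n_depths: int = 5,
    eps: float = 1e-6,
) -> np.ndarray:
    """Mean T1w/T2w over equally spaced depths on the white-to-pial segment.

    Samples with |T2w| < eps are excluded; vertices with no valid sample are
    returned as NaN (flagged missing).
    """
    if len(white.vertices) != len(pial.vertices):
        raise ValidationError("white/pial vertex mismatch")
    if not np.any(np.abs(t2w.values) >= eps):
        raise ValidationError("T2w volume is identically ~zero")
    fracs = np.linspace(0.0, 1.0, n_depths)
    n = len(white.vertices)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for f in fracs:
        pts = (1 - f) * white.vertices + f * pial.vertices
        v1 = sample_scalar(t1w.values, t1w.grid, pts)
        v2 = sample_scalar(t2w.values, t2w.grid, pts)
        ok = np.abs(v2) >= eps
        acc[ok] += v1[ok] / v2[ok]
        cnt[ok] += 1
    out = np.full(n, np.nan)
    good = cnt > 0
    out[good] = acc[good] / cnt[good]
    return out
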