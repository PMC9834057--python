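"""Attribute-driven registration of spherical maps.

A deliberately minimal demons-style registration on the unit sphere: each
moving vertex takes tangential steps along the gradient of the fixed
attribute field, scaled by the local attribute difference, with graph-based
Gaussian smoothing of the update field and reprojection to the sphere.
Average convexity drives the coarse levels; mean curvature is added at the
finest level.  Steps that would fold a spherical triangle are halved (up to
10 times) and otherwise rejected for the offending vertices; iterations
that do not decrease the mean squared attribute difference are rejected, so
the objective is non-increasing.

Precomputed vertex-wise correspondences can be supplied instead (e.g. from
an external spherical registration tool) via :func:`load_correspondences`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError
from .surface import (
    SphericalMap,
    TriangleMesh,
    _adjacency,
    _spherical_orient,
    locate_on_sphere,
    resample_attribute_on_sphere,
)

__all__ = [
    "SphericalWarp",
    "RegistrationError",
    "register_spherical_maps",
    "propagate_to_anatomical",
    "load_correspondences",
    "save_correspondences",
]

log = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


@dataclass
class SphericalWarp:
    """Warped position of each moving vertex on the unit sphere."""

    target_positions: np.ndarray  # (N, 3) unit vectors

    def __post_init__(self):
        self.target_positions = np.asarray(self.target_positions, dtype=float)
        n = np.linalg.norm(self.target_positions, axis=1)
        if np.abs(n - 1.0).max() > 1e-6:
            raise ValidationError("warp targets must be unit vectors")


def _mean_edge_length(positions: np.ndarray, triangles: np.ndarray) -> float:
    e = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    e = np.unique(e, axis=0)
    return float(np.linalg.norm(positions[e[:, 0]] - positions[e[:, 1]], axis=1).mean())


def _graph_smooth(values: np.ndarray, A, n_iter: int) -> np.ndarray:
    """Gaussian-like smoothing by iterated neighbor averaging."""
    out = values.copy()
    for _ in range(max(0, n_iter)):
        out = 0.5 * (out + A @ out)
    return out


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


def _triangle_gradients(positions: np.ndarray, triangles: np.ndarray, values: np.ndarray):
    """Per-triangle 3D gradient of a piecewise-linear attribute."""
    p0, p1, p2 = (positions[triangles[:, k]] for k in range(3))
    v0, v1, v2 = (values[triangles[:, k]] for k in range(3))
    e1, e2 = p1 - p0, p2 - p0
    n = np.cross(e1, e2)
    nn = (n * n).sum(axis=1)
    nn = np.where(nn == 0, 1.0, nn)
    # gradient of the linear interpolant within the triangle plane:
    # grad f = (v1-v0) (e2 x n)/|n|^2 + (v2-v0) (n x e1)/|n|^2
    g = ((v1 - v0)[:, None] * np.cross(e2, n) + (v2 - v0)[:, None] * np.cross(n, e1)) / nn[:, None]
    return g


def register_spherical_maps(
    moving: SphericalMap,
    fixed: SphericalMap,
    n_levels: int = 3,
    step: float = 0.1,
    smooth_sigma: float = 2.0,
    max_iter_per_level: int = 60,
    rel_tol: float = 1e-4,
) -> SphericalWarp:
    """Register `moving` to `fixed` using convexity (+ curvature at finest level).

    `step` and `smooth_sigma` are in units of the moving mesh's mean edge
    length.  Attributes are z-score normalized internally.
    """
    if moving.convexity is None or fixed.convexity is None:
        raise ValidationError("both maps need a convexity attribute")
    has_curv = moving.curvature is not None and fixed.curvature is not None

    mov_tris = moving.triangles
    A = _adjacency(TriangleMesh(moving.positions, mov_tris))
    edge = _mean_edge_length(moving.positions, mov_tris)
    pos = moving.positions.copy()

    # attribute smoothing schedule (coarse -> fine), in neighbor-avg rounds
    smooth_rounds = [2 ** (n_levels - 1 - lv) * 4 for lv in range(n_levels)]
    smooth_rounds[-1] = 0
    upd_rounds = max(1, int(round((smooth_sigma) ** 2)))

    A_fix = _adjacency(TriangleMesh(fixed.positions, fixed.triangles))

    for lv in range(n_levels):
        attrs_mov, attrs_fix = [], []
        pairs = [(moving.convexity, fixed.convexity)]
        if lv == n_levels - 1 and has_curv:
            pairs.append((moving.curvature, fixed.curvature))
        for am, af in pairs:
            attrs_mov.append(_graph_smooth(_zscore(am), A, smooth_rounds[lv]))
            attrs_fix.append(_graph_smooth(_zscore(af), A_fix, smooth_rounds[lv]))

        fix_grads = [
            _triangle_gradients(fixed.positions, fixed.triangles, af) for af in attrs_fix
        ]

        def objective(p):
            tri, bc = locate_on_sphere(fixed.positions, fixed.triangles, p)
            total = 0.0
            for am, af in zip(attrs_mov, attrs_fix):
                vals = (af[fixed.triangles[tri]] * bc).sum(axis=1)
                total += float(((am - vals) ** 2).mean())
            return total / len(attrs_mov), tri, bc

        obj, tri_cur, bc_cur = objective(pos)
        step_len = step * edge
        for _ in range(max_iter_per_level):
            tri, bc = tri_cur, bc_cur
            update = np.zeros_like(pos)
            for am, af, g in zip(attrs_mov, attrs_fix, fix_grads):
                vals = (af[fixed.triangles[tri]] * bc).sum(axis=1)
                diff = am - vals
                grad = g[tri]
                gnorm2 = (grad * grad).sum(axis=1)
                # demons-style normalized step toward decreasing (diff)^2
                update += diff[:, None] * grad / (gnorm2 + diff**2 + 1e-12)[:, None]
            update = _graph_smooth(update, A, upd_rounds)
            # tangential projection and length cap
            update -= (update * pos).sum(axis=1, keepdims=True) * pos
            mag = np.linalg.norm(update, axis=1)
            # single global scale (keeps the update field smooth), max = step_len
            update *= min(1.0, step_len / max(float(mag.max()), 1e-12))
            trial = pos + update
            trial /= np.linalg.norm(trial, axis=1, keepdims=True)
            # unfold: halve offending vertices' motion, then cascade-revert
            for _half in range(10):
                bad = _spherical_orient(trial, mov_tris) <= 0
                if not bad.any():
                    break
                bad_verts = np.unique(mov_tris[bad])
                trial[bad_verts] = 0.5 * (trial[bad_verts] + pos[bad_verts])
                trial[bad_verts] /= np.linalg.norm(
                    trial[bad_verts], axis=1, keepdims=True
                )
            else:
                # full revert cascades until fold-free (terminates: reverting
                # everything reproduces the fold-free previous positions)
                for _ in range(len(pos)):
                    bad = _spherical_orient(trial, mov_tris) <= 0
                    if not bad.any():
                        break
                    bad_verts = np.unique(mov_tris[bad])
                    trial[bad_verts] = pos[bad_verts]
                else:  # pragma: no cover
                    raise RegistrationError("unresolvable fold during registration")
            new_obj, tri_new, bc_new = objective(trial)
            if new_obj > obj:
                step_len *= 0.5
                if step_len < 1e-4 * edge:
                    break
                continue
            improved = (obj - new_obj) / max(obj, 1e-300)
            pos = trial
            obj = new_obj
            tri_cur, bc_cur = tri_new, bc_new
            if improved < rel_tol:
                break

    if (_spherical_orient(pos, mov_tris) <= 0).any():
        raise RegistrationError("folded triangles in final warp")
    return SphericalWarp(pos)


def propagate_to_anatomical(
    warp: SphericalWarp,
    moving_white: TriangleMesh,
    moving_pial: TriangleMesh,
    fixed_white: TriangleMesh,
    fixed_pial: TriangleMesh,
    fixed_sphere: SphericalMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-wise anatomical displacements implied by a spherical warp.

    For each moving vertex, its warped spherical position is located in the
    fixed sphere's triangulation and the fixed white/pial coordinates are
    interpolated barycentrically.  Returns (white, pial) displacement arrays
    in mm: interpolated fixed position minus moving position.
    """
    disp = []
    for mov, fix in ((moving_white, fixed_white), (moving_pial, fixed_pial)):
        interp = resample_attribute_on_sphere(
            fixed_sphere, fix.vertices, warp.target_positions
        )
        disp.append(interp - mov.vertices)
    return disp[0], disp[1]


def save_correspondences(warp: SphericalWarp, path) -> None:
    np.savetxt(path, warp.target_positions, delimiter=",", header="x,y,z", comments="")


def load_correspondences(path) -> SphericalWarp:
    """Per-vertex target spherical coordinates from a CSV table (x,y,z)."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return SphericalWarp(arr)
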