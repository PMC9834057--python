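"""Core spatial data types, displacement-field algebra and neuroimaging I/O.

Conventions (fixed package-wide):

* All grids are axis-aligned RAS; the world coordinate of voxel index ``v``
  is ``origin + v * spacing``.  Oblique orientation matrices are rejected.
* A displacement field ``phi`` stores millimetre vectors on the fixed grid
  and induces the deformation ``Phi(x) = x + phi(x)``.  Warping follows the
  pull-back (resampling) convention: the output value at ``x`` is the input
  sampled at ``x + phi(x)``, trilinearly, with zero extension outside the
  domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "TissueProbMap",
    "LabelVolume",
    "DisplacementField",
    "AffineTransform",
    "GridError",
    "ConvergenceError",
    "ValidationError",
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
    "TISSUE_CHANNELS",
    "compose_displacements",
    "invert_displacement",
    "warp_scalar_volume",
    "warp_tissue_map",
    "warp_label_volume",
    "apply_affine_to_volume",
    "apply_affine_to_tissue_map",
    "affine_to_displacement",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
    "read_surface_arrays",
    "write_surface_arrays",
    "read_subject_meta",
    "write_subject_meta",
]

# Tissue label coding, fixed by configuration default.
LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
#: channel order of TissueProbMap arrays
TISSUE_CHANNELS = ("WM", "GM", "CSF")


class GridError(ValueError):
    """Grids are incompatible (shape, spacing or origin differ)."""


class ConvergenceError(RuntimeError):
    """An iterative routine failed to reach its tolerance."""


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned sampling lattice in world millimetres."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValidationError(f"bad grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    # -- coordinate helpers -------------------------------------------------
    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical side lengths of the grid (mm)."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    def world_coords(self) -> np.ndarray:
        """(X, Y, Z, 3) array of voxel-center world coordinates."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        ).astype(float)
        return self.origin_arr + idx * self.spacing_arr

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (..., 3)."""
        return (np.asarray(pts, dtype=float) - self.origin_arr) / self.spacing_arr

    def compatible(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise GridError(f"incompatible grids: {self} vs {other}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 voxel-to-world matrix (diagonal by construction)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


@dataclass
class ScalarVolume:
    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"value shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        _check_finite(self.values, "ScalarVolume")


@dataclass
class TissueProbMap:
    """Per-voxel probabilities over (WM, GM, CSF); remainder is background."""

    grid: VoxelGrid
    channels: np.ndarray  # (X, Y, Z, 3)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape != self.grid.shape + (3,):
            raise ValidationError(
                f"channel shape {self.channels.shape} != {self.grid.shape + (3,)}"
            )
        _check_finite(self.channels, "TissueProbMap")
        if self.channels.min() < -1e-6 or self.channels.max() > 1 + 1e-6:
            raise ValidationError("tissue probabilities outside [0, 1]")
        if self.channels.sum(axis=-1).max() > 1 + 1e-6:
            raise ValidationError("tissue probabilities sum above 1")

    @property
    def background(self) -> np.ndarray:
        return np.clip(1.0 - self.channels.sum(axis=-1), 0.0, 1.0)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[..., TISSUE_CHANNELS.index(name)]


@dataclass
class LabelVolume:
    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValidationError("label shape mismatch")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise ValidationError(f"unknown label codes {sorted(bad)}")


@dataclass
class DisplacementField:
    grid: VoxelGrid
    vectors: np.ndarray  # (X, Y, Z, 3), mm

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValidationError("vector shape mismatch")
        _check_finite(self.vectors, "DisplacementField")

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Trilinear sample of the vector field at world points (zero outside)."""
        return sample_vectors(self.vectors, self.grid, pts)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass(frozen=True)
class AffineTransform:
    """Forward world-space map x -> matrix @ x + translation."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.matrix.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("affine must be 3x3 matrix + 3-vector")
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValidationError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def as_params(self) -> np.ndarray:
        """Row-major 3x4 flattened to 12 numbers (matrix | translation)."""
        return np.hstack([self.matrix, self.translation[:, None]]).ravel()

    @classmethod
    def from_params(cls, params) -> "AffineTransform":
        p = np.asarray(params, dtype=float).reshape(3, 4)
        return cls(p[:, :3], p[:, 3])


# --------------------------------------------------------------------------
# field algebra
# --------------------------------------------------------------------------


def _sample_channels(values: np.ndarray, grid: VoxelGrid, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of (X,Y,Z[,C]) values at world points (...,3)."""
    idx = grid.world_to_index(pts)
    flat = idx.reshape(-1, 3).T  # (3, N)
    # grid-constant: genuine trilinear interpolation against a zero padding
    if values.ndim == 3:
        out = map_coordinates(values, flat, order=1, mode="grid-constant", cval=0.0)
        return out.reshape(idx.shape[:-1])
    chans = [
        map_coordinates(values[..., c], flat, order=1, mode="grid-constant", cval=0.0)
        for c in range(values.shape[-1])
    ]
    return np.stack(chans, axis=-1).reshape(idx.shape[:-1] + (values.shape[-1],))


def sample_scalar(values: np.ndarray, grid: VoxelGrid, pts: np.ndarray) -> np.ndarray:
    if _numba is not None:
        out = trilinear_channels(values[..., None], grid, np.asarray(pts, dtype=float))
        return out[..., 0]
    return _sample_channels(values, grid, pts)


try:  # numba accelerates the solver's inner loop; numpy path is equivalent
    import numba as _numba

    @_numba.njit(cache=False, fastmath=True)
    def _trilinear_kernel(vals, idx, out):  # pragma: no cover - jitted
        nx, ny, nz, nc = vals.shape
        for i in range(idx.shape[0]):
            x0 = int(np.floor(idx[i, 0]))
            y0 = int(np.floor(idx[i, 1]))
            z0 = int(np.floor(idx[i, 2]))
            fx = idx[i, 0] - x0
            fy = idx[i, 1] - y0
            fz = idx[i, 2] - z0
            for c in range(nc):
                acc = 0.0
                for dx in range(2):
                    xi = x0 + dx
                    if xi < 0 or xi >= nx:
                        continue
                    wx = fx if dx == 1 else 1.0 - fx
                    for dy in range(2):
                        yi = y0 + dy
                        if yi < 0 or yi >= ny:
                            continue
                        wy = fy if dy == 1 else 1.0 - fy
                        for dz in range(2):
                            zi = z0 + dz
                            if zi < 0 or zi >= nz:
                                continue
                            wz = fz if dz == 1 else 1.0 - fz
                            acc += wx * wy * wz * vals[xi, yi, zi, c]
                out[i, c] = acc

except ImportError:  # pragma: no cover
    _numba = None


def trilinear_channels(values: np.ndarray, grid: VoxelGrid, pts: np.ndarray) -> np.ndarray:
    """Fused multi-channel trilinear sampling with zero extension.

    Equivalent to :func:`_sample_channels` for (X,Y,Z,C) arrays; hot path of
    the registration solver.
    """
    if _numba is None:
        return _sample_channels(values, grid, pts)
    idx = grid.world_to_index(pts.reshape(-1, 3))
    out = np.empty((idx.shape[0], values.shape[-1]))
    _trilinear_kernel(np.ascontiguousarray(values), idx, out)
    return out.reshape(pts.shape[:-1] + (values.shape[-1],))


def sample_vectors(vectors: np.ndarray, grid: VoxelGrid, pts: np.ndarray) -> np.ndarray:
    if _numba is not None:
        return trilinear_channels(vectors, grid, np.asarray(pts, dtype=float))
    return _sample_channels(vectors, grid, pts)


def compose_displacements(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Field of ``Phi_outer o Phi_inner`` (inner applied first).

    r(x) = phi_inner(x) + phi_outer(x + phi_inner(x)).
    """
    outer.grid.require_compatible(inner.grid)
    x = inner.grid.world_coords()
    mid = x + inner.vectors
    r = inner.vectors + sample_vectors(outer.vectors, outer.grid, mid)
    return DisplacementField(inner.grid, r)


def _interior_mask(shape: tuple[int, int, int], margin: int = 1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, n - margin) for n in shape)
    m[sl] = True
    return m


def invert_displacement(
    field: DisplacementField, max_iter: int = 50, tol: float = 1e-3
) -> DisplacementField:
    """Fixed-point inverse: psi <- -phi(x + psi(x)).

    The returned field satisfies ``|phi(x + psi(x)) + psi(x)| <= tol`` over
    interior voxels, i.e. ``Phi o Psi ~= id``.
    """
    grid = field.grid
    max_disp = np.abs(field.vectors).max(axis=(0, 1, 2))
    if np.any(max_disp >= grid.extent_mm / 2.0):
        raise ValidationError(
            "displacement too large for fixed-point inversion "
            f"(max per-axis {max_disp}, extent {grid.extent_mm})"
        )
    x = grid.world_coords()
    psi = -field.vectors.copy()
    interior = _interior_mask(grid.shape)
    resid = np.inf
    for _ in range(max_iter):
        phi_at = sample_vectors(field.vectors, grid, x + psi)
        residual = phi_at + psi
        resid = np.abs(residual[interior]).max() if interior.any() else 0.0
        if resid <= tol:
            return DisplacementField(grid, psi)
        psi = -phi_at
    raise ConvergenceError(
        f"displacement inversion did not reach tol={tol} after {max_iter} "
        f"iterations (residual {resid:.3e} mm)"
    )


def invert_displacement_best_effort(
    field: DisplacementField, max_iter: int = 100, relax: float = 0.5
) -> DisplacementField:
    """Under-relaxed fixed-point inversion that never raises.

    Where the deformation folds (no exact inverse exists) the iteration
    settles on a pseudo-inverse; callers should verify the residual at the
    locations they care about.
    """
    grid = field.grid
    x = grid.world_coords()
    psi = -field.vectors.copy()
    for _ in range(max_iter):
        phi_at = sample_vectors(field.vectors, grid, x + psi)
        psi = (1.0 - relax) * psi + relax * (-phi_at)
    return DisplacementField(grid, psi)


def inversion_residual_at(
    field: DisplacementField, inverse: DisplacementField, pts: np.ndarray
) -> np.ndarray:
    """|phi(p + psi(p)) + psi(p)| at world points (mm)."""
    psi_at = sample_vectors(inverse.vectors, inverse.grid, pts)
    phi_at = sample_vectors(field.vectors, field.grid, pts + psi_at)
    return np.linalg.norm(phi_at + psi_at, axis=-1)


def warp_scalar_volume(image: ScalarVolume, field: DisplacementField) -> ScalarVolume:
    """Pull-back warp: out(x) = image(x + phi(x))."""
    image.grid.require_compatible(field.grid)
    x = field.grid.world_coords()
    out = sample_scalar(image.values, image.grid, x + field.vectors)
    return ScalarVolume(field.grid, out)


def warp_tissue_map(tmap: TissueProbMap, field: DisplacementField) -> TissueProbMap:
    tmap.grid.require_compatible(field.grid)
    x = field.grid.world_coords()
    out = trilinear_channels(tmap.channels, tmap.grid, x + field.vectors) if _numba is not None else _sample_channels(tmap.channels, tmap.grid, x + field.vectors)
    out = np.clip(out, 0.0, 1.0)
    s = out.sum(axis=-1, keepdims=True)
    # renormalize only genuine interpolation overshoot (sums within the
    # validity tolerance are left untouched so identity warps are bitwise)
    np.divide(out, s, out=out, where=s > 1.0 + 1e-6)
    return TissueProbMap(field.grid, out)


def warp_label_volume(lab: LabelVolume, field: DisplacementField) -> LabelVolume:
    """Nearest-neighbour warp for integer label maps."""
    lab.grid.require_compatible(field.grid)
    x = field.grid.world_coords() + field.vectors
    idx = lab.grid.world_to_index(x).reshape(-1, 3).T
    out = map_coordinates(lab.labels.astype(float), idx, order=0, mode="constant", cval=0)
    return LabelVolume(field.grid, out.reshape(lab.grid.shape).astype(np.int16))


def apply_affine_to_volume(
    image: ScalarVolume, affine: AffineTransform, target_grid: VoxelGrid
) -> ScalarVolume:
    """Resample under the pull-back convention: out(x) = image(affine^{-1}(x))."""
    inv = affine.inverse()
    pts = inv.apply(target_grid.world_coords().reshape(-1, 3))
    vals = sample_scalar(image.values, image.grid, pts).reshape(target_grid.shape)
    return ScalarVolume(target_grid, vals)


def apply_affine_to_tissue_map(
    tmap: TissueProbMap, affine: AffineTransform, target_grid: VoxelGrid
) -> TissueProbMap:
    inv = affine.inverse()
    pts = inv.apply(target_grid.world_coords().reshape(-1, 3))
    vals = trilinear_channels(tmap.channels, tmap.grid, pts) if _numba is not None else _sample_channels(tmap.channels, tmap.grid, pts)
    vals = np.clip(vals.reshape(target_grid.shape + (3,)), 0.0, 1.0)
    s = vals.sum(axis=-1, keepdims=True)
    np.divide(vals, s, out=vals, where=s > 1.0 + 1e-6)
    return TissueProbMap(target_grid, vals)


def affine_to_displacement(
    affine: AffineTransform, grid: VoxelGrid
) -> DisplacementField:
    """Pull-back displacement field equivalent to affine resampling on `grid`.

    warp with the returned field == apply_affine_to_volume(affine):
    x + phi(x) = affine^{-1}(x).
    """
    inv = affine.inverse()
    x = grid.world_coords()
    return DisplacementField(grid, inv.apply(x.reshape(-1, 3)).reshape(x.shape) - x)


# --------------------------------------------------------------------------
# I/O: NIfTI volumes, GIfTI surfaces, JSON metadata
# --------------------------------------------------------------------------


def _grid_from_nifti(img) -> VoxelGrid:
    aff = img.affine
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-4 * max(1.0, np.abs(lin).max()):
        raise ValidationError(
            "oblique/sheared orientation matrices are not supported "
            "(axis-aligned RAS grids only)"
        )
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise ValidationError("negative or zero voxel spacing in orientation matrix")
    shape = img.shape[:3]
    return VoxelGrid(tuple(shape), tuple(diag), tuple(aff[:3, 3]))


def read_volume(path) -> ScalarVolume | TissueProbMap | LabelVolume:
    """Read a NIfTI-1 volume.

    3D integer data -> LabelVolume, 3D float -> ScalarVolume,
    4D with 3 channels -> TissueProbMap (channel order WM, GM, CSF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 3:
            raise ValidationError(
                f"4D volume must have 3 channels (WM,GM,CSF), got {data.shape[3]}"
            )
        return TissueProbMap(grid, np.clip(data.astype(float), 0.0, 1.0))
    if data.ndim != 3:
        raise ValidationError(f"expected 3D or 4D volume, got {data.ndim}D")
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(grid, data.astype(np.int16))
    return ScalarVolume(grid, data.astype(float))


def write_volume(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ScalarVolume):
        data, dtype = obj.values, np.float32
    elif isinstance(obj, TissueProbMap):
        data, dtype = obj.channels, np.float32
    elif isinstance(obj, LabelVolume):
        data, dtype = obj.labels, np.int16
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as a volume")
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), obj.grid.affine)
    nib.save(img, str(path))


def read_displacement_field(path) -> DisplacementField:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValidationError("displacement field must be 4D with 3 components")
    return DisplacementField(grid, data)


def write_displacement_field(field: DisplacementField, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(field.vectors.astype(np.float32), field.grid.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_surface_arrays(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read a GIfTI surface: (vertices, triangles, named per-vertex attributes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gii = nib.load(str(path))
    verts = tris = None
    attrs: dict[str, np.ndarray] = {}
    for arr in gii.darrays:
        intent = nib.nifti1.intent_codes.label[arr.intent]
        if intent == "pointset":
            verts = np.asarray(arr.data, dtype=float)
        elif intent == "triangle":
            tris = np.asarray(arr.data, dtype=int)
        else:
            name = arr.meta.get("Name", f"attr{len(attrs)}")
            attrs[name] = np.asarray(arr.data, dtype=float)
    if verts is None or tris is None:
        raise ValidationError(f"{path} lacks a pointset/triangle pair")
    if tris.ndim != 2 or tris.shape[1] != 3:
        raise ValidationError("non-triangle faces in surface file")
    for name, a in attrs.items():
        if a.shape[0] != verts.shape[0]:
            raise ValidationError(f"attribute {name!r} length != vertex count")
    return verts, tris, attrs


def write_surface_arrays(vertices, triangles, path, attributes=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gii = nib.gifti.GiftiImage()
    gii.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            np.asarray(vertices, dtype=np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    gii.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            np.asarray(triangles, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    for name, arr in (attributes or {}).items():
        da = nib.gifti.GiftiDataArray(
            np.asarray(arr, dtype=np.float32), intent="NIFTI_INTENT_SHAPE"
        )
        da.meta["Name"] = name
        gii.add_gifti_data_array(da)
    nib.save(gii, str(path))


def read_subject_meta(path) -> dict:
    with open(path) as f:
        meta = json.load(f)
    if "age_months" not in meta:
        raise ValidationError(f"{path} lacks 'age_months'")
    return meta


def write_subject_meta(meta: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(meta, f, indent=2, sort_keys=True)
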