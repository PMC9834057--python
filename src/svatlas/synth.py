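"""Synthetic longitudinal cohort of folded brain phantoms.

The generator emulates the study design this package targets: staggered
enrolment cohorts with first visits at 2 weeks, 1, 2, 9, 10 and 11 months,
follow-up scans every 3 months during the first year and a final scan at
24 months; age-dependent T1w/T2w tissue contrast that crosses zero inside
the isointense windows (T1w around 3-6 months, T2w around 9-12 months); and
logistic tissue-growth curves.  Phantoms are star-shaped two-hemisphere
"brains": the white surface is a spherical-harmonic-folded ellipsoid, the
pial surface a radial offset of it, and tissue probability maps are
rasterized exactly from the same radius functions, so surfaces and volumes
are consistent by construction and all ground truths (volumes, thickness,
contrast crossings) are analytically recoverable.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.special import sph_harm_y

from .data_model import DisplacementField, ScalarVolume, TissueProbMap, VoxelGrid
from .subjects import HemiSurfaces, SubjectScan
from .surface import TriangleMesh, vertex_areas

__all__ = [
    "LogisticCurve",
    "GrowthModel",
    "CohortSpec",
    "make_icosphere",
    "make_phantom",
    "make_longitudinal_cohort",
    "make_known_deformation",
    "default_grid",
]


def default_grid(n: int = 48, spacing: float = 2.0) -> VoxelGrid:
    """Desk-scale grid centred on the origin."""
    half = (n - 1) * spacing / 2.0
    return VoxelGrid((n, n, n), (spacing, spacing, spacing), (-half, -half, -half))


# --------------------------------------------------------------------------
# growth model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticCurve:
    """baseline + asymptote / (1 + exp(-rate * (age - midpoint)))."""

    baseline: float
    asymptote: float
    rate: float  # 1/month
    midpoint: float  # months

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        return self.baseline + self.asymptote / (1.0 + np.exp(-self.rate * (age - self.midpoint)))

    def derivative(self, age):
        age = np.asarray(age, dtype=float)
        e = np.exp(-self.rate * (age - self.midpoint))
        return self.asymptote * self.rate * e / (1.0 + e) ** 2

    @property
    def peak_velocity_age(self) -> float:
        return self.midpoint


def _default_volume_curves() -> dict[str, LogisticCurve]:
    # Desk-scale volumes (mL) shaped to yield roughly +95% first-year and
    # +13% second-year whole-brain growth, the regime the method targets.
    shape = dict(rate=0.22, midpoint=4.0)
    return {
        "WM": LogisticCurve(baseline=0.235 * 20.2, asymptote=20.2, **shape),
        "GM": LogisticCurve(baseline=0.235 * 31.3, asymptote=31.3, **shape),
        "CSF": LogisticCurve(baseline=0.235 * 1.5, asymptote=1.5, **shape),
    }


@dataclass(frozen=True)
class GrowthModel:
    """Prescribed tissue growth, contrast and folding curves."""

    volume_curves_ml: dict[str, LogisticCurve] = field(
        default_factory=_default_volume_curves
    )
    #: WM-GM intensity difference as a function of age; crosses zero at the
    #: centre of the isointense window.
    t1_contrast_amp: float = 25.0
    t1_cross_age: float = 4.5
    t1_cross_width: float = 3.0
    t2_contrast_amp: float = 25.0
    t2_cross_age: float = 10.5
    t2_cross_width: float = 3.5
    gm_t1_mean: float = 100.0
    gm_t2_mean: float = 120.0
    csf_t1_mean: float = 40.0
    csf_t2_mean: float = 180.0
    noise_sd: float = 3.0
    #: relative radial fold amplitude (dimensionless fraction of radius)
    fold_amp: LogisticCurve = LogisticCurve(0.05, 0.05, 0.22, 4.0)
    csf_shell_mm: float = 2.0

    def __post_init__(self):
        ages = np.linspace(0.5, 24.0, 48)
        for name, c in self.volume_curves_ml.items():
            if np.any(c(ages) <= 0):
                raise ValueError(f"{name} volume curve not positive on [0.5, 24]")

    # -- prescribed ground truths ------------------------------------------
    def volume_ml(self, tissue: str, age) -> np.ndarray:
        return self.volume_curves_ml[tissue](age)

    def wm_minus_gm_t1(self, age):
        return self.t1_contrast_amp * np.tanh(
            (np.asarray(age, dtype=float) - self.t1_cross_age) / self.t1_cross_width
        )

    def wm_minus_gm_t2(self, age):
        return -self.t2_contrast_amp * np.tanh(
            (np.asarray(age, dtype=float) - self.t2_cross_age) / self.t2_cross_width
        )

    def tissue_means(self, age) -> dict[str, tuple[float, float]]:
        """(T1w, T2w) mean intensity per tissue at `age`."""
        return {
            "WM": (
                self.gm_t1_mean + float(self.wm_minus_gm_t1(age)),
                self.gm_t2_mean + float(self.wm_minus_gm_t2(age)),
            ),
            "GM": (self.gm_t1_mean, self.gm_t2_mean),
            "CSF": (self.csf_t1_mean, self.csf_t2_mean),
        }

    def percent_change(self, tissue: str, t_start: float, t_end: float) -> float:
        c = self.volume_curves_ml[tissue]
        return float(100.0 * (c(t_end) - c(t_start)) / c(t_start))


# --------------------------------------------------------------------------
# cohort schedule
# --------------------------------------------------------------------------

FIRST_VISITS = (0.5, 1.0, 2.0, 9.0, 10.0, 11.0)  # 2 weeks encoded as 0.5 months


def visit_schedule(first_visit: float) -> list[float]:
    """Visits every 3 months up to 12 months, plus a 24-month scan."""
    ages = []
    a = first_visit
    while a <= 12.0 + 1e-9:
        ages.append(round(a, 2))
        a += 3.0
    ages.append(24.0)
    return ages


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 12
    seed: int = 0
    first_visits: tuple[float, ...] = FIRST_VISITS

    def __post_init__(self):
        for v in self.first_visits:
            if not (0.5 <= v <= 24.0):
                raise ValueError(f"first visit {v} outside [0.5, 24] months")

    def subject_plan(self) -> list[tuple[str, float, list[float]]]:
        """(subject id, first visit, visit ages) per subject, round-robin cohorts."""
        plan = []
        for i in range(self.n_subjects):
            fv = self.first_visits[i % len(self.first_visits)]
            plan.append((f"sub-{i:03d}", fv, visit_schedule(fv)))
        return plan


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------


def make_icosphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Closed genus-0 icosphere with 10*4^s + 2 vertices."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=int))


def _real_sph_harm(l: int, m: int, dirs: np.ndarray) -> np.ndarray:
    """Real spherical harmonic evaluated at unit direction vectors."""
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


# fixed fold pattern shared by every subject (so folds correspond across the
# cohort); low-order harmonics give reproducible sulci/gyri
_FOLD_TERMS = ((3, 2, 1.0), (4, 1, 0.7), (4, 3, 0.6), (5, 4, 0.5), (5, 2, 0.4))


def _fold_pattern(dirs: np.ndarray) -> np.ndarray:
    f = np.zeros(len(dirs))
    for l, m, c in _FOLD_TERMS:
        f += c * _real_sph_harm(l, m, dirs)
    return f / np.abs(f).max() if np.abs(f).max() > 0 else f


@dataclass(frozen=True)
class _SubjectShape:
    """Seeded per-subject anatomical perturbation, fixed across visits."""

    coeffs: tuple  # ((l, m, c), ...) radial perturbation harmonics
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # mm
    scale: float

    @classmethod
    def sample(cls, rng: np.random.Generator, rel_amp: float = 0.03) -> "_SubjectShape":
        terms = []
        for l in range(1, 5):
            for m in range(-l, l + 1):
                terms.append((l, m, rng.normal(0.0, rel_amp / (l + 1))))
        angle = np.deg2rad(rng.uniform(-4.0, 4.0))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = rng.uniform(-2.0, 2.0, size=3)
        s = float(np.exp(rng.normal(0.0, 0.02)))
        return cls(tuple(terms), R, t, s)

    def perturbation(self, dirs: np.ndarray) -> np.ndarray:
        p = np.zeros(len(dirs))
        for l, m, c in self.coeffs:
            if c != 0.0:
                p += c * _real_sph_harm(l, m, dirs)
        return p


# ellipsoid axis ratios of one hemisphere (x = left-right)
_HEMI_AXES = np.array([0.55, 0.85, 0.75])


def _quadrature_dirs(subdiv: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions and solid-angle weights for radial volume integrals."""
    ico = make_icosphere(subdiv, 1.0)
    return ico.vertices, vertex_areas(ico)


_QUAD_DIRS, _QUAD_W = None, None


def _get_quadrature():
    global _QUAD_DIRS, _QUAD_W
    if _QUAD_DIRS is None:
        _QUAD_DIRS, _QUAD_W = _quadrature_dirs(3)
    return _QUAD_DIRS, _QUAD_W


class _HemiGeometry:
    """Radius functions of one hemisphere at one age."""

    def __init__(self, growth: GrowthModel, age: float, shape: _SubjectShape):
        dirs, w = _get_quadrature()
        self.shape = shape
        amp = float(growth.fold_amp(age))
        ellip = 1.0 / np.sqrt(((dirs / _HEMI_AXES) ** 2).sum(axis=1))
        g = ellip * (1.0 + amp * _fold_pattern(dirs) + shape.perturbation(dirs))
        # per-hemisphere target volumes (mm^3); WM volume excludes the ventricle
        v_wm = 1000.0 * float(growth.volume_ml("WM", age)) / 2.0
        v_gm = 1000.0 * float(growth.volume_ml("GM", age)) / 2.0
        v_vent = 1000.0 * float(growth.volume_ml("CSF", age)) / 2.0
        int_g3 = float((w * g**3).sum()) / 3.0
        self.r_base = ((v_wm + v_vent) / int_g3) ** (1.0 / 3.0)
        # cortical thickness t solves the GM shell volume integral
        int_g2 = float((w * g**2).sum())
        int_g1 = float((w * g).sum())
        # (1/3) int ((R g + t)^3 - (R g)^3) dOmega = v_gm  (cubic in t)
        coeffs = [
            4.0 * np.pi / 3.0,
            self.r_base * int_g1,
            self.r_base**2 * int_g2,
            -v_gm,
        ]
        roots = np.roots(coeffs)
        real = roots[np.abs(roots.imag) < 1e-9].real
        self.thickness = float(real[real > 0].min())
        self.vent_radius = (v_vent / (4.0 * np.pi / 3.0)) ** (1.0 / 3.0)
        self.amp = amp

    def white_radius(self, dirs: np.ndarray) -> np.ndarray:
        ellip = 1.0 / np.sqrt(((dirs / _HEMI_AXES) ** 2).sum(axis=1))
        g = ellip * (
            1.0 + self.amp * _fold_pattern(dirs) + self.shape.perturbation(dirs)
        )
        return self.r_base * g

    def pial_radius(self, dirs: np.ndarray) -> np.ndarray:
        return self.white_radius(dirs) + self.thickness


def _hemi_centers(geoms) -> dict[str, np.ndarray]:
    gap = 2.0
    offsets = {}
    for hemi, sgn in (("lh", -1.0), ("rh", 1.0)):
        half_width = geoms[hemi].r_base * _HEMI_AXES[0]
        offsets[hemi] = np.array([sgn * (half_width + gap / 2.0), 0.0, 0.0])
    return offsets


def make_phantom(
    age: float,
    growth: GrowthModel,
    grid: VoxelGrid,
    seed: int = 0,
    subject_id: str = "sub-000",
    cohort: str = "",
    mesh_subdivisions: int = 3,
    shape: _SubjectShape | None = None,
) -> SubjectScan:
    """Folded two-hemisphere brain phantom with paired volumes and surfaces."""
    rng = np.random.default_rng(seed)
    if shape is None:
        shape = _SubjectShape.sample(rng)
    noise_rng = np.random.default_rng([seed, int(round(age * 100)), 7])

    geoms = {h: _HemiGeometry(growth, age, shape) for h in ("lh", "rh")}
    centers = _hemi_centers(geoms)

    # head-frame transform (per-subject rigid + scale jitter)
    R, t, s = shape.rotation, shape.translation, shape.scale

    # --- surfaces ----------------------------------------------------------
    ico = make_icosphere(mesh_subdivisions, 1.0)
    dirs_v = ico.vertices
    surfaces = {}
    for hemi in ("lh", "rh"):
        g = geoms[hemi]
        rw = g.white_radius(dirs_v)
        rp = g.pial_radius(dirs_v)
        white0 = centers[hemi] + rw[:, None] * dirs_v
        pial0 = centers[hemi] + rp[:, None] * dirs_v
        white = (s * (R @ white0.T)).T + t
        pial = (s * (R @ pial0.T)).T + t
        surfaces[hemi] = HemiSurfaces(
            TriangleMesh(white, ico.triangles.copy()),
            TriangleMesh(pial, ico.triangles.copy()),
        )

    # --- tissue rasterization (exact radial inside/outside tests) ----------
    x = grid.world_coords().reshape(-1, 3)
    # undo the head-frame transform so anatomy is evaluated in canonical frame
    x0 = ((x - t) @ R) / s  # R^T = inverse of rotation
    wm = np.zeros(len(x), dtype=float)
    gm = np.zeros(len(x), dtype=float)
    csf = np.zeros(len(x), dtype=float)
    for hemi in ("lh", "rh"):
        g = geoms[hemi]
        d = x0 - centers[hemi]
        r = np.linalg.norm(d, axis=1)
        rsafe = np.where(r == 0, 1.0, r)
        u = d / rsafe[:, None]
        # evaluate radius functions only near the hemisphere to save time
        near = r <= (g.r_base * 1.8 + g.thickness + growth.csf_shell_mm + 4.0)
        rw = np.zeros(len(x))
        rw[near] = g.white_radius(u[near])
        rp = rw + g.thickness
        inside_white = near & (r <= rw)
        in_vent = near & (r <= g.vent_radius)
        wm = np.maximum(wm, (inside_white & ~in_vent).astype(float))
        gm = np.maximum(gm, (near & (r > rw) & (r <= rp)).astype(float))
        shell = near & (r > rp) & (r <= rp + growth.csf_shell_mm)
        csf = np.maximum(csf, (in_vent | shell).astype(float))

    shp = grid.shape
    sig = 0.8  # voxels; symmetric partial-volume smoothing
    wm = gaussian_filter(wm.reshape(shp), sig)
    gm = gaussian_filter(gm.reshape(shp), sig)
    csf = gaussian_filter(csf.reshape(shp), sig)
    chans = np.stack([wm, gm, csf], axis=-1)
    ssum = chans.sum(axis=-1, keepdims=True)
    np.divide(chans, ssum, out=chans, where=ssum > 1.0)
    chans = np.clip(chans, 0.0, 1.0)
    tissue = TissueProbMap(grid, chans)

    # --- intensities --------------------------------------------------------
    means = growth.tissue_means(age)
    t1 = np.zeros(shp)
    t2 = np.zeros(shp)
    for i, name in enumerate(("WM", "GM", "CSF")):
        t1 += chans[..., i] * means[name][0]
        t2 += chans[..., i] * means[name][1]
    t1 += noise_rng.normal(0.0, growth.noise_sd, shp)
    t2 += noise_rng.normal(0.0, growth.noise_sd, shp)

    return SubjectScan(
        subject_id=subject_id,
        age_months=float(age),
        t1w=ScalarVolume(grid, t1),
        t2w=ScalarVolume(grid, t2),
        tissue=tissue,
        surfaces=surfaces,
        cohort=cohort,
        info={
            # per-subject ground truths: the rigid+scale jitter multiplies all
            # prescribed volumes by scale^3
            "volume_scale": float(s**3),
            "thickness_mm": float(geoms["lh"].thickness * s),
            "fold_amplitude": float(geoms["lh"].amp),
        },
    )


def make_longitudinal_cohort(
    spec: CohortSpec,
    growth: GrowthModel | None = None,
    grid: VoxelGrid | None = None,
    mesh_subdivisions: int = 3,
) -> list[SubjectScan]:
    """Longitudinal cohort on the staggered-enrolment schedule.

    Each subject keeps one fixed anatomical perturbation across visits;
    output is deterministic under ``spec.seed``.
    """
    growth = growth or GrowthModel()
    grid = grid or default_grid()
    scans = []
    for i, (sid, fv, ages) in enumerate(spec.subject_plan()):
        subj_seed = spec.seed * 100003 + i
        shape = _SubjectShape.sample(np.random.default_rng(subj_seed))
        for age in ages:
            scans.append(
                make_phantom(
                    age,
                    growth,
                    grid,
                    seed=subj_seed,
                    subject_id=sid,
                    cohort=f"first-visit-{fv}",
                    mesh_subdivisions=mesh_subdivisions,
                    shape=shape,
                )
            )
    return scans


def make_blob_phantom(
    grid: VoxelGrid,
    seed: int = 7,
    blob_sigma_vox: float = 2.5,
    ball_radius_mm: float = 36.0,
) -> TissueProbMap:
    """Two-tissue registration-validation phantom.

    Random smooth blob texture thresholded into interleaved WM/GM patches
    inside a ball: tissue interfaces occur densely and in all orientations,
    so a known deformation is recoverable everywhere (no aperture
    ambiguity), which is what a solver-recovery experiment needs.
    """
    x = grid.world_coords()
    r = np.linalg.norm(x, axis=-1)
    rng = np.random.default_rng(seed)
    s = gaussian_filter(rng.normal(size=grid.shape), blob_sigma_vox)
    ball = r < ball_radius_mm
    wm = gaussian_filter(((s > 0) & ball).astype(float), 0.8)
    gm = gaussian_filter(((s <= 0) & ball).astype(float), 0.8)
    chans = np.clip(np.stack([wm, gm, np.zeros_like(wm)], axis=-1), 0.0, 1.0)
    ssum = chans.sum(axis=-1, keepdims=True)
    np.divide(chans, ssum, out=chans, where=ssum > 1.0)
    return TissueProbMap(grid, chans)


def make_known_deformation(
    grid: VoxelGrid, max_mm: float, smoothness_mm: float, seed: int = 0
) -> DisplacementField:
    """Smooth random displacement field, zero at the boundary, |phi|max = max_mm."""
    extent = grid.extent_mm.min()
    if max_mm >= extent / 4.0:
        raise ValueError(f"max_mm {max_mm} too large for grid extent {extent}")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=grid.shape + (3,))
    sig = [smoothness_mm / s for s in grid.spacing]
    for c in range(3):
        raw[..., c] = gaussian_filter(raw[..., c], sig)
    # taper to exactly zero on the boundary
    taper = np.ones(grid.shape)
    for ax, n in enumerate(grid.shape):
        f = np.sin(np.pi * np.arange(n) / (n - 1))
        sl = [None, None, None]
        sl[ax] = slice(None)
        taper = taper * f[tuple(sl)]
    raw *= taper[..., None]
    # boundary voxels exactly zero (taper reaches sin(pi) only up to rounding)
    for ax in range(3):
        sl = [slice(None)] * 4
        sl[ax] = 0
        raw[tuple(sl)] = 0.0
        sl[ax] = -1
        raw[tuple(sl)] = 0.0
    mag = np.linalg.norm(raw, axis=-1).max()
    if mag > 0:
        raw *= max_mm / mag
    return DisplacementField(grid, raw)
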