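"""Subject-level and atlas-level container types and their on-disk layout.

A subject visit directory holds ``t1w.nii.gz``, ``t2w.nii.gz``,
``tissue.nii.gz`` (4D, channels WM/GM/CSF), ``{lh,rh}_{white,pial}.gii`` and
``meta.json`` (id, age in months, cohort label).  An atlas directory uses the
same layout plus ``tissue_label.nii.gz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (
    LabelVolume,
    ScalarVolume,
    TissueProbMap,
    read_subject_meta,
    read_volume,
    read_surface_arrays,
    write_subject_meta,
    write_surface_arrays,
    write_volume,
)
from .surface import TriangleMesh

__all__ = ["HemiSurfaces", "SubjectScan", "AtlasBundle", "HEMIS", "SURF_NAMES"]

HEMIS = ("lh", "rh")
SURF_NAMES = ("white", "pial")


@dataclass
class HemiSurfaces:
    """White + pial meshes of one hemisphere with shared vertex correspondence."""

    white: TriangleMesh
    pial: TriangleMesh

    def __post_init__(self):
        if len(self.white.vertices) != len(self.pial.vertices):
            raise ValueError("white/pial surfaces must share vertex count")

    def copy(self) -> "HemiSurfaces":
        return HemiSurfaces(self.white.copy(), self.pial.copy())


@dataclass
class SubjectScan:
    """One visit: age, intensity volumes, tissue map, surfaces per hemisphere."""

    subject_id: str
    age_months: float
    t1w: ScalarVolume
    t2w: ScalarVolume
    tissue: TissueProbMap
    surfaces: dict[str, HemiSurfaces] = field(default_factory=dict)
    cohort: str = ""
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, float]:
        return (self.subject_id, float(self.age_months))

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        write_volume(self.t1w, outdir / "t1w.nii.gz")
        write_volume(self.t2w, outdir / "t2w.nii.gz")
        write_volume(self.tissue, outdir / "tissue.nii.gz")
        for hemi, hs in self.surfaces.items():
            write_surface_arrays(
                hs.white.vertices, hs.white.triangles, outdir / f"{hemi}_white.gii"
            )
            write_surface_arrays(
                hs.pial.vertices, hs.pial.triangles, outdir / f"{hemi}_pial.gii"
            )
        write_subject_meta(
            {
                "subject_id": self.subject_id,
                "age_months": self.age_months,
                "cohort": self.cohort,
                "info": self.info,
            },
            outdir / "meta.json",
        )

    @classmethod
    def load(cls, indir) -> "SubjectScan":
        indir = Path(indir)
        meta = read_subject_meta(indir / "meta.json")
        surfaces = {}
        for hemi in HEMIS:
            wpath = indir / f"{hemi}_white.gii"
            if wpath.exists():
                wv, wt, _ = read_surface_arrays(wpath)
                pv, pt, _ = read_surface_arrays(indir / f"{hemi}_pial.gii")
                surfaces[hemi] = HemiSurfaces(
                    TriangleMesh(wv, wt), TriangleMesh(pv, pt)
                )
        return cls(
            subject_id=str(meta["subject_id"]),
            age_months=float(meta["age_months"]),
            t1w=read_volume(indir / "t1w.nii.gz"),
            t2w=read_volume(indir / "t2w.nii.gz"),
            tissue=read_volume(indir / "tissue.nii.gz"),
            surfaces=surfaces,
            cohort=str(meta.get("cohort", "")),
            info=dict(meta.get("info", {})),
        )


@dataclass
class AtlasBundle:
    """Age-stamped surface atlas + volumetric atlases in one coordinate frame."""

    age_months: float
    t1w: ScalarVolume
    t2w: ScalarVolume
    tissue_prob: TissueProbMap
    tissue_label: LabelVolume
    surfaces: dict[str, HemiSurfaces]

    def __post_init__(self):
        g = self.t1w.grid
        for other in (self.t2w.grid, self.tissue_prob.grid, self.tissue_label.grid):
            g.require_compatible(other)
        for hs in self.surfaces.values():
            if len(hs.white.vertices) != len(hs.pial.vertices):
                raise ValueError("white/pial vertex mismatch in atlas bundle")

    def tissue_volumes_ml(self) -> dict[str, float]:
        """GM/WM/CSF/WBV volumes in mL from the probabilistic atlas."""
        vv = self.tissue_prob.grid.voxel_volume / 1000.0  # mm^3 -> mL
        gm = float(self.tissue_prob.channel("GM").sum() * vv)
        wm = float(self.tissue_prob.channel("WM").sum() * vv)
        csf = float(self.tissue_prob.channel("CSF").sum() * vv)
        return {"GM": gm, "WM": wm, "CSF": csf, "WBV": gm + wm}

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        write_volume(self.t1w, outdir / "t1w.nii.gz")
        write_volume(self.t2w, outdir / "t2w.nii.gz")
        write_volume(self.tissue_prob, outdir / "tissue_prob.nii.gz")
        write_volume(self.tissue_label, outdir / "tissue_label.nii.gz")
        for hemi, hs in self.surfaces.items():
            for name, mesh in (("white", hs.white), ("pial", hs.pial)):
                write_surface_arrays(
                    mesh.vertices,
                    mesh.triangles,
                    outdir / f"{hemi}_{name}.gii",
                    attributes={
                        k: v
                        for k, v in mesh.attributes.items()
                        if np.ndim(v) == 1 and len(v) == len(mesh.vertices)
                    },
                )
        write_subject_meta({"subject_id": "atlas", "age_months": self.age_months},
                           outdir / "meta.json")

    @classmethod
    def load(cls, indir) -> "AtlasBundle":
        indir = Path(indir)
        meta = read_subject_meta(indir / "meta.json")
        surfaces = {}
        for hemi in HEMIS:
            if not (indir / f"{hemi}_white.gii").exists():
                continue
            wv, wt, wa = read_surface_arrays(indir / f"{hemi}_white.gii")
            pv, pt, pa = read_surface_arrays(indir / f"{hemi}_pial.gii")
            surfaces[hemi] = HemiSurfaces(
                TriangleMesh(wv, wt, wa), TriangleMesh(pv, pt, pa)
            )
        if not surfaces:
            raise FileNotFoundError(f"no surface files in {indir}")
        return cls(
            age_months=float(meta["age_months"]),
            t1w=read_volume(indir / "t1w.nii.gz"),
            t2w=read_volume(indir / "t2w.nii.gz"),
            tissue_prob=read_volume(indir / "tissue_prob.nii.gz"),
            tissue_label=read_volume(indir / "tissue_label.nii.gz"),
            surfaces=surfaces,
        )
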