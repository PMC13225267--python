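"""File I/O: NIfTI masks and distance fields, VTK polydata, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import DistanceField, ShapeModel, VolumeMask


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_mask(mask: VolumeMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> VolumeMask:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError(f"{path}: only axis-aligned RAS affines are supported")
    spacing = tuple(np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: negative spacing; reorient to RAS first")
    return VolumeMask(np.asarray(img.dataobj) > 0, spacing,
                      origin=tuple(aff[:3, 3]))


def save_field(field: DistanceField, path: str | Path,
               sidecar: dict | None = None) -> None:
    img = nib.Nifti1Image(field.grid.astype(np.float32),
                          _affine(field.spacing, field.origin))
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_field(path: str | Path) -> DistanceField:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(np.diag(aff[:3, :3]))
    return DistanceField(np.asarray(img.dataobj, dtype=np.float32), spacing,
                         origin=tuple(aff[:3, 3]))


def write_vtk_polydata(path: str | Path, points: np.ndarray,
                       faces: np.ndarray | None = None,
                       normals: np.ndarray | None = None,
                       point_scalars: dict[str, np.ndarray] | None = None
                       ) -> None:
    """Minimal legacy-ASCII VTK polydata writer (points, polys, point data)."""
    points = np.asarray(points, dtype=float)
    lines = ["# vtk DataFile Version 3.0", "mtasym surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(points)} float"]
    lines += [" ".join(f"{v:.6f}" for v in p) for p in points]
    if faces is not None and len(faces):
        faces = np.asarray(faces, dtype=int)
        lines.append(f"POLYGONS {len(faces)} {len(faces) * 4}")
        lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    data_blocks = []
    if normals is not None:
        data_blocks.append("NORMALS normals float")
        data_blocks += [" ".join(f"{v:.6f}" for v in n) for n in normals]
    for name, vals in (point_scalars or {}).items():
        data_blocks.append(f"SCALARS {name} float 1")
        data_blocks.append("LOOKUP_TABLE default")
        data_blocks += [f"{float(v):.6g}" for v in vals]
    if data_blocks:
        lines.append(f"POINT_DATA {len(points)}")
        lines += data_blocks
    Path(path).write_text("\n".join(lines) + "\n")


def save_shape_model(model: ShapeModel, outdir: str | Path) -> None:
    """Export template and per-subject point sets (VTK + CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    verts, faces = model.template_mesh
    write_vtk_polydata(outdir / "template_mesh.vtk", verts, faces)
    write_vtk_polydata(outdir / "template_points.vtk", model.template_points,
                       normals=model.template_normals)
    tpl = pd.DataFrame(
        np.hstack([model.template_points, model.template_normals]),
        columns=["x", "y", "z", "nx", "ny", "nz"])
    tpl.index.name = "index"
    tpl.to_csv(outdir / "template_points.csv")
    rows = []
    for (pid, side), pts in sorted(model.subject_points.items()):
        df = pd.DataFrame(pts, columns=["x", "y", "z"])
        df.insert(0, "participant_id", pid)
        df.insert(1, "side", side)
        df.insert(2, "index", np.arange(len(pts)))
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "subject_points.csv", index=False)


def save_asymmetry(table, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.point_asym.to_csv(outdir / f"{table.structure}_point_asym.csv")
    vols = table.volumes.copy()
    vols["volume_asym"] = table.volume_asym
    if table.volumes_raw is not None:
        vols["left_raw"] = table.volumes_raw["left"]
        vols["right_raw"] = table.volumes_raw["right"]
    vols.to_csv(outdir / f"{table.structure}_volumes.csv")
    meta = {"structure": table.structure, "n_points": table.n_points,
            **table.meta}
    (outdir / f"{table.structure}_asym_meta.json").write_text(
        json.dumps(meta, indent=2, default=str))
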