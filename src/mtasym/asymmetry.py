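"""Directional left-to-right shape asymmetry and volume-asymmetry indices.

Sign convention (matches the usual green/purple rendering): a positive
per-point asymmetry means the left surface lies *outside* the mirrored
right surface at that point, i.e. the left structure is locally larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grooming import groomed_volume
from .types import DistanceField, PipelineError, ShapeModel, VolumeMask


def directional_asymmetry(left_points: np.ndarray,
                          right_flipped_points: np.ndarray,
                          normals: np.ndarray) -> np.ndarray:
    """Per-point scalar asymmetry a(k) = (left_k - right_k) . n_k  (mm).

    All three arrays share the template index k; normals must be unit length.
    """
    normals = np.asarray(normals, dtype=float)
    lens = np.linalg.norm(normals, axis=1)
    if not np.allclose(lens, 1.0, atol=1e-6):
        raise PipelineError("normals are not unit length")
    diff = np.asarray(left_points, dtype=float) - np.asarray(
        right_flipped_points, dtype=float)
    return np.einsum("ij,ij->i", diff, normals)


def structure_volume(mask: VolumeMask) -> float:
    """Volume in mm^3: foreground voxel count times voxel volume."""
    n = mask.n_foreground
    if n == 0:
        raise PipelineError("empty mask has no volume")
    return n * mask.voxel_volume


def volume_asymmetry(vol_left: float, vol_right: float) -> float:
    """(L - R) / (L + R): dimensionless, antisymmetric, bounded in [-1, 1]."""
    total = vol_left + vol_right
    if total <= 0:
        raise PipelineError("both volumes are zero")
    return (vol_left - vol_right) / total


@dataclass
class AsymmetryTable:
    """Per-participant point asymmetries and volume-asymmetry indices."""

    structure: str
    point_asym: pd.DataFrame          # participants x M, mm
    volume_asym: pd.Series            # participant -> (L-R)/(L+R)
    volumes: pd.DataFrame             # participant x {left, right}, mm^3
    volumes_raw: pd.DataFrame | None = None   # pre-grooming voxel volumes
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.point_asym.shape[1]

    def participants(self) -> list[str]:
        return list(self.point_asym.index)


def build_asymmetry_table(model: ShapeModel,
                          groomed: dict[tuple[str, str], DistanceField],
                          raw_masks: dict[tuple[str, str], VolumeMask] | None = None,
                          ) -> AsymmetryTable:
    """Assemble the asymmetry table from a shape model and groomed fields.

    ``groomed`` maps (participant_id, side) with side in {"left",
    "right_flipped"} to distance fields (same keys as the model).  Volumes
    are computed from the groomed fields for consistency with the shape
    processing; raw voxel-count volumes are reported alongside when the
    original masks are supplied.
    """
    pids = sorted({pid for pid, _ in model.subject_points})
    rows = []
    vol_l, vol_r, asym = {}, {}, {}
    for pid in pids:
        lp = model.subject_points[(pid, "left")]
        rp = model.subject_points[(pid, "right_flipped")]
        rows.append(directional_asymmetry(lp, rp, model.template_normals))
        vol_l[pid] = groomed_volume(groomed[(pid, "left")])
        vol_r[pid] = groomed_volume(groomed[(pid, "right_flipped")])
        asym[pid] = volume_asymmetry(vol_l[pid], vol_r[pid])
    point_asym = pd.DataFrame(
        np.vstack(rows), index=pids,
        columns=[f"p{k:04d}" for k in range(model.n_points)])
    point_asym.index.name = "participant_id"
    volumes = pd.DataFrame({"left": vol_l, "right": vol_r})
    volumes.index.name = "participant_id"
    volumes_raw = None
    if raw_masks is not None:
        volumes_raw = pd.DataFrame({
            "left": {p: structure_volume(raw_masks[(p, "left")]) for p in pids},
            "right": {p: structure_volume(raw_masks[(p, "right")]) for p in pids},
        })
        volumes_raw.index.name = "participant_id"
    return AsymmetryTable(structure=model.structure,
                          point_asym=point_asym,
                          volume_asym=pd.Series(asym, name="volume_asym"),
                          volumes=volumes,
                          volumes_raw=volumes_raw,
                          meta={"n_points": model.n_points})
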