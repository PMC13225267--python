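"""Core containers shared across the pipeline.

Conventions
-----------
* Grids are indexed ``(x, y, z)`` with the first axis the left-right (sagittal)
  axis of an RAS frame.  World coordinates of voxel ``(i, j, k)`` are
  ``origin + (i, j, k) * spacing`` in millimetres.
* Signed distances are negative inside the structure and positive outside;
  outward surface normals therefore point along the positive gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

GROUPS = ("AD_Epi", "nonAD_Epi", "AD_NoEpi", "nonAD_NoEpi", "HC")
STRUCTURES = ("hippocampus", "amygdala")
SIDES = ("left", "right")

#: number of correspondence points per structure
DEFAULT_N_POINTS = {"hippocampus": 512, "amygdala": 256}


class PipelineError(RuntimeError):
    """Raised when a pipeline stage receives input it cannot process."""


@dataclass
class VolumeMask:
    """Binary 3-D segmentation of one structure in one hemisphere.

    Parameters
    ----------
    grid
        Boolean voxel array, axis order (x, y, z), x = left-right.
    spacing
        Voxel edge lengths in mm.
    origin
        World coordinate of voxel (0, 0, 0) in mm.
    orientation
        Axis codes; only "RAS" is produced and accepted.
    meta
        Free-form provenance (synthetic shape parameters, ground-truth
        region frame, participant/side labels).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def copy(self) -> "VolumeMask":
        return VolumeMask(self.grid.copy(), self.spacing, self.origin,
                          self.orientation, dict(self.meta))


@dataclass
class DistanceField:
    """Signed-distance representation of a groomed shape (mm, negative inside)."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate vectors of the voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.grid.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def copy(self) -> "DistanceField":
        return DistanceField(self.grid.copy(), self.spacing, self.origin,
                             self.orientation, dict(self.meta))


@dataclass
class RigidTransform:
    """Rotation + translation mapping subject coordinates into the template frame:
    ``x_template = R @ x_subject + t``."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.R.T + self.t

    def invert(self, points: np.ndarray) -> np.ndarray:
        """Map template-frame points back into the subject frame."""
        return (points - self.t) @ self.R

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ShapeModel:
    """Mirrored correspondence-point model for one structure.

    ``subject_points`` maps ``(participant_id, side)`` with
    ``side in {"left", "right_flipped"}`` to an (M, 3) array of corresponded
    surface points in the shared template frame.
    """

    structure: str
    n_points: int
    template_points: np.ndarray
    template_normals: np.ndarray
    template_mesh: tuple[np.ndarray, np.ndarray]  # (vertices, faces)
    subject_points: dict[tuple[str, str], np.ndarray]
    transforms: dict[tuple[str, str], RigidTransform]
    fallback_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    mean_field: "DistanceField | None" = None
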