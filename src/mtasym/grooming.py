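"""Grooming: binary masks -> smooth signed-distance fields on an isotropic grid.

The stages mirror standard particle-shape-model preprocessing: antialias the
binary interface, resample every participant to a common isotropic
resolution, convert to a signed-distance transform (negative inside), and
apply a mild Gaussian blur for numerical stability.  Shapes whose groomed
mask is empty or splits into several components are rejected with a logged
reason (stand-in for visual quality control).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage

from .types import DistanceField, PipelineError, VolumeMask

log = logging.getLogger(__name__)

#: default grooming parameters (declared, not inferred from any dataset)
DEFAULT_ITERATIONS = 3
DEFAULT_ISO_SPACING = 1.0
DEFAULT_BLUR_SIGMA = 0.5       # mm
_ANTIALIAS_SIGMA_VOX = 0.4     # per-iteration Gaussian width, voxels

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def validate_mask(mask: VolumeMask) -> None:
    """Reject empty or fragmented segmentations."""
    if mask.n_foreground == 0:
        raise PipelineError("empty mask")
    _, n = ndimage.label(mask.grid, structure=_STRUCT6)
    if n != 1:
        raise PipelineError(f"mask has {n} connected components (expected 1)")


def antialias(mask: VolumeMask,
              smoothing_iterations: int = DEFAULT_ITERATIONS) -> np.ndarray:
    """Iterated Gaussian smoothing of the binary indicator, clipped to [0, 1].

    Thresholding the result at 0.5 recovers a mask whose volume differs from
    the input by well under 2% for smooth shapes.
    """
    if mask.n_foreground == 0:
        raise PipelineError("cannot antialias an empty mask")
    g = mask.grid.astype(np.float32)
    # n sequential Gaussian passes equal one pass at sigma * sqrt(n)
    sigma = _ANTIALIAS_SIGMA_VOX * np.sqrt(int(smoothing_iterations))
    if sigma > 0:
        g = ndimage.gaussian_filter(g, sigma)
    np.clip(g, 0.0, 1.0, out=g)
    if not (g >= 0.5).any():
        warnings.warn("antialiased shape vanished at the 0.5 level; "
                      "shape will be rejected by grooming")
    return g


def resample_isotropic(grid: np.ndarray,
                       spacing_in: tuple[float, float, float],
                       spacing_out: float) -> np.ndarray:
    """Trilinear resampling onto an isotropic grid, preserving physical extent."""
    if spacing_out <= 0:
        raise ValueError("spacing_out must be > 0")
    fg = grid >= 0.5
    if fg.any():
        idx = np.where(fg)
        extents = [(i.max() - i.min() + 1) * s
                   for i, s in zip(idx, spacing_in)]
        if spacing_out > min(extents):
            raise PipelineError(
                f"target spacing {spacing_out} mm exceeds the smallest object "
                f"dimension ({min(extents):.1f} mm)")
    factors = [s / spacing_out for s in spacing_in]
    if np.allclose(factors, 1.0):
        return grid.astype(np.float32, copy=True)
    return ndimage.zoom(grid.astype(np.float32), factors, order=1,
                        mode="nearest", grid_mode=True)


def signed_distance(grid: np.ndarray, spacing: float,
                    iso: float = 0.5) -> np.ndarray:
    """Signed Euclidean distance (mm) to the iso-surface; negative inside.

    Voxel distances come from exact Euclidean distance transforms of the two
    phases; voxels adjacent to the interface are refined with a sub-voxel
    correction from the antialiased values.
    """
    inside = grid >= iso
    if inside.all() or (~inside).all():
        raise PipelineError("grid is single-phase; no iso-surface present")
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    sd = (d_out - d_in).astype(np.float32)
    # near the interface |d_out - d_in| == 1 voxel; use the smooth indicator
    # and its local gradient to place the surface at sub-voxel accuracy
    band = np.abs(sd) <= 1.5 * spacing
    if band.any():
        gx, gy, gz = np.gradient(grid.astype(np.float32), spacing)
        gm = np.sqrt(gx[band] ** 2 + gy[band] ** 2 + gz[band] ** 2)
        sub = (iso - grid[band]) / np.maximum(gm, 1e-3)
        sd[band] = np.clip(sub, -1.5 * spacing, 1.5 * spacing)
    return sd


def gaussian_blur(field: DistanceField, sigma: float) -> DistanceField:
    """Mild Gaussian blur of the distance field (sigma in mm; 0 is identity)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return field.copy()
    sig_vox = [sigma / s for s in field.spacing]
    out = field.copy()
    out.grid = ndimage.gaussian_filter(field.grid, sig_vox)
    out.meta["blur_sigma_mm"] = float(sigma)
    return out


def groom(mask: VolumeMask,
          iso_spacing: float = DEFAULT_ISO_SPACING,
          smoothing_iterations: int = DEFAULT_ITERATIONS,
          blur_sigma: float = DEFAULT_BLUR_SIGMA) -> DistanceField:
    """Full grooming pipeline: validate, antialias, resample, SDT, blur."""
    validate_mask(mask)
    g = antialias(mask, smoothing_iterations)
    g = resample_isotropic(g, mask.spacing, iso_spacing)
    if not (g >= 0.5).any():
        raise PipelineError("shape vanished during grooming")
    lbl, n = ndimage.label(g >= 0.5, structure=_STRUCT6)
    if n != 1:
        raise PipelineError(
            f"groomed shape split into {n} components; rejected")
    sd = signed_distance(g, iso_spacing)
    field = DistanceField(sd, (iso_spacing,) * 3, origin=mask.origin,
                          meta={**{k: v for k, v in mask.meta.items()
                                   if k != "sdf"},
                                "groom": {"iterations": smoothing_iterations,
                                          "iso_spacing": iso_spacing,
                                          "blur_sigma": blur_sigma}})
    return gaussian_blur(field, blur_sigma)


def groomed_volume(field: DistanceField) -> float:
    """Volume (mm^3) of the groomed shape, from voxels inside the zero level."""
    return float((field.grid < 0).sum() * np.prod(field.spacing))
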