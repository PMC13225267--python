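"""Shared fixtures: analytic distance fields and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from mtasym.types import DistanceField, VolumeMask


def sphere_field(radius: float, n: int = 41, spacing: float = 1.0,
                 shift=(0.0, 0.0, 0.0)) -> DistanceField:
    """Exact signed-distance field of a sphere centred in an n^3 grid."""
    c = np.array([(n - 1) / 2 * spacing] * 3) + np.asarray(shift, float)
    ax = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - radius
    return DistanceField(d.astype(np.float32), (spacing,) * 3)


def ellipsoid_field(semi, n: int = 51, spacing: float = 1.0, rot=None,
                    shift=(0.0, 0.0, 0.0)) -> DistanceField:
    """Approximate SDF of an ellipsoid, optionally rotated/shifted."""
    c = np.array([(n - 1) / 2 * spacing] * 3) + np.asarray(shift, float)
    ax = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) - c
    if rot is not None:
        pts = pts @ rot          # inverse-rotate sample points
    a, b, cc = semi
    q = np.sqrt((pts[..., 0] / a) ** 2 + (pts[..., 1] / b) ** 2
                + (pts[..., 2] / cc) ** 2)
    g = np.sqrt((pts[..., 0] / a ** 2) ** 2 + (pts[..., 1] / b ** 2) ** 2
                + (pts[..., 2] / cc ** 2) ** 2)
    f = np.where(g > 1e-9, (q - 1) * q / np.maximum(g, 1e-9), -min(semi))
    return DistanceField(f.astype(np.float32), (spacing,) * 3)


def sphere_mask(radius: float, n: int = 41, spacing: float = 1.0) -> VolumeMask:
    return VolumeMask(sphere_field(radius, n, spacing).grid < 0,
                      (spacing,) * 3)


def rotation_z(degrees: float) -> np.ndarray:
    th = np.deg2rad(degrees)
    return np.array([[np.cos(th), -np.sin(th), 0.0],
                     [np.sin(th), np.cos(th), 0.0],
                     [0.0, 0.0, 1.0]])


@pytest.fixture(scope="session")
def mirror_null_cohort():
    """Tiny perfectly mirrored cohort (no baseline, no noise, no effects)."""
    from mtasym.synthetic import CohortConfig, generate_cohort
    cfg = CohortConfig(n_per_group={"HC": 3, "AD_Epi": 3},
                       structures=("hippocampus",), seed=11,
                       baseline_asym_mm=0.0, noise_sigma_mm=0.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small five-group cohort with baseline asymmetry and noise, no effects."""
    from mtasym.synthetic import CohortConfig, generate_cohort
    cfg = CohortConfig(
        n_per_group={g: 8 for g in ("AD_Epi", "nonAD_Epi", "AD_NoEpi",
                                    "nonAD_NoEpi", "HC")},
        structures=("hippocampus",), seed=5,
        baseline_asym_mm=0.1, noise_sigma_mm=0.5)
    return generate_cohort(cfg)
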