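"""Synthetic cohorts of paired left/right mesial temporal segmentations.

Real study data of this kind (clinical MRI with FreeSurfer segmentations of
hippocampus and amygdala) cannot be redistributed, so every downstream stage
is exercised on generated cohorts with *known* ground truth:

* each structure is a smooth implicit surface (a curved ellipsoid for the
  hippocampus, a plain ellipsoid for the amygdala) voxelized on a millimetre
  grid;
* a small uniform inward offset of the left surface reproduces the normative
  "left slightly smaller than right" hemispheric asymmetry;
* group-specific effects are localized inward deformations (Gaussian bumps)
  of one side's surface, centred on a named anatomical region
  (hippocampal head / body / tail, lateral / medial amygdala);
* measurement noise is a spatially smooth random displacement of the surface.

Because the deformations are applied to the implicit function before
thresholding, the ground-truth location and sign of every injected effect is
known exactly, and amplitude 0 reproduces the null generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import GROUPS, PipelineError, VolumeMask

log = logging.getLogger(__name__)

HIPPOCAMPUS_REGIONS = ("head", "body", "tail")
AMYGDALA_REGIONS = ("lateral", "medial")

#: default axis lengths (full extents, mm) of the base shapes
DEFAULT_HIPPOCAMPUS_AXES = (40.0, 15.0, 12.0)
DEFAULT_AMYGDALA_AXES = (18.0, 14.0, 12.0)
DEFAULT_BEND = 0.4  # radians; gentle banana-like curvature of the hippocampus


@dataclass(frozen=True)
class EffectSpec:
    """A localized ground-truth asymmetry effect.

    The surface of ``side_shrunk`` is displaced inward by a Gaussian bump of
    height ``amplitude`` (mm) and width ``spatial_sigma`` (mm) centred on the
    named region, for participants in ``affected_groups`` only.
    ``amplitude = 0`` is a no-op, so the null generator is the special case.
    """

    structure: str
    region: str
    side_shrunk: str
    amplitude: float
    spatial_sigma: float = 4.0
    affected_groups: frozenset[str] = frozenset(GROUPS)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("effect amplitude must be >= 0")
        if self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be > 0")
        regions = (HIPPOCAMPUS_REGIONS if self.structure == "hippocampus"
                   else AMYGDALA_REGIONS if self.structure == "amygdala"
                   else None)
        if regions is None:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.region not in regions:
            raise ValueError(
                f"unknown region {self.region!r} for {self.structure}")
        if self.side_shrunk not in ("left", "right"):
            raise ValueError("side_shrunk must be 'left' or 'right'")
        object.__setattr__(self, "affected_groups",
                           frozenset(self.affected_groups))


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to reproduce a synthetic cohort.

    The seed fully determines all masks and covariates.  Default group sizes
    follow the study design the generator emulates (63 epilepsy cases split
    35/28 by dementia type, 1:5 matched dementia-only and healthy-control
    pools of 320 each, split 183/137 for the dementia pool).
    """

    n_per_group: Mapping[str, int] = field(default_factory=lambda: {
        "AD_Epi": 35, "nonAD_Epi": 28,
        "AD_NoEpi": 183, "nonAD_NoEpi": 137, "HC": 320,
    })
    baseline_asym_mm: float = 0.1
    noise_sigma_mm: float = 0.5
    noise_smooth_mm: float = 2.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    effects: tuple[EffectSpec, ...] = ()
    structures: tuple[str, ...] = ("hippocampus", "amygdala")
    hippocampus_axes: tuple[float, float, float] = DEFAULT_HIPPOCAMPUS_AXES
    amygdala_axes: tuple[float, float, float] = DEFAULT_AMYGDALA_AXES
    bend: float = DEFAULT_BEND
    margin_mm: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_group", dict(self.n_per_group))
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "structures", tuple(self.structures))
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")


# ---------------------------------------------------------------------------
# implicit base shapes
# ---------------------------------------------------------------------------

def _check_axes(axes: Iterable[float], spacing: Iterable[float]) -> None:
    for ax, sp in zip(axes, spacing):
        if ax <= 2.0 * sp:
            raise PipelineError("structure thinner than voxel grid")


def _centered_coords(shape: tuple[int, int, int],
                     spacing: tuple[float, float, float]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [ (np.arange(n) - (n - 1) / 2.0) * s
             for n, s in zip(shape, spacing) ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_sdf(X, Y, Z, semi: tuple[float, float, float]) -> np.ndarray:
    """First-order approximation of the signed distance to an ellipsoid (mm)."""
    a, b, c = semi
    q = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    # |grad q| wrt mm coordinates = |(x/a^2, y/b^2, z/c^2)| / q
    g = np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2 + (Z / c**2) ** 2)
    f = np.where(g > 1e-9, (q - 1.0) * q / np.maximum(g, 1e-9),
                 (q - 1.0) * min(a, b, c))
    return f.astype(np.float32)


def _bend_kappa(bend: float, semi_a: float) -> float:
    # quadratic shear y -> y + kappa x^2; slope at the tip equals tan(bend),
    # Jacobian is 1 so the deformation is exactly volume preserving
    return math.tan(bend) / (2.0 * semi_a)


def _hippocampus_field(shape, spacing, axes, bend) -> np.ndarray:
    a, b, c = (ax / 2.0 for ax in axes)
    X, Y, Z = _centered_coords(shape, spacing)
    kappa = _bend_kappa(bend, a)
    Yc = Y - kappa * X ** 2
    return _ellipsoid_sdf(X, Yc, Z, (a, b, c))


def _grid_shape(axes, spacing, margin, sag=0.0) -> tuple[int, int, int]:
    extents = (axes[0] + 2 * margin,
               axes[1] + 2 * sag + 2 * margin,
               axes[2] + 2 * margin)
    return tuple(int(math.ceil(e / s)) | 1 for e, s in zip(extents, spacing))


def base_implicit_field(kind: str,
                        spacing: tuple[float, float, float],
                        axes: tuple[float, float, float],
                        bend: float = 0.0,
                        margin_mm: float = 4.0) -> tuple[np.ndarray, dict]:
    """Evaluate the base implicit (approximate signed distance) on a tight grid."""
    _check_axes(axes, spacing)
    a = axes[0] / 2.0
    sag = a * math.tan(bend) / 2.0 if kind == "hippocampus" else 0.0
    shape = _grid_shape(axes, spacing, margin_mm, sag)
    if kind == "hippocampus":
        f = _hippocampus_field(shape, spacing, axes, bend)
    elif kind == "amygdala":
        semi = tuple(ax / 2.0 for ax in axes)
        X, Y, Z = _centered_coords(shape, spacing)
        f = _ellipsoid_sdf(X, Y, Z, semi)
    else:
        raise ValueError(f"unknown structure {kind!r}")
    params = {"kind": kind, "axes": tuple(map(float, axes)),
              "bend": float(bend), "shape": shape,
              "spacing": tuple(map(float, spacing))}
    return f, params


def _mask_from_field(f: np.ndarray, spacing, params: dict) -> VolumeMask:
    grid = f < 0.0
    meta = {"shape_params": params, "sdf": f}
    return VolumeMask(grid, spacing, origin=(0.0, 0.0, 0.0), meta=meta)


def generate_base_hippocampus(spacing=(1.0, 1.0, 1.0),
                              size_params=DEFAULT_HIPPOCAMPUS_AXES,
                              bend: float = 0.0) -> VolumeMask:
    """Curved-ellipsoid hippocampus surrogate.

    The long axis is x; the normalized coordinate t = (x - x_min) / length
    splits the structure into head (t < 1/3), body, and tail (t > 2/3).
    Bending is a quadratic shear of y against x and preserves volume exactly
    in the continuum.
    """
    f, params = base_implicit_field("hippocampus", spacing, size_params, bend)
    mask = _mask_from_field(f, spacing, params)
    if mask.n_foreground == 0:
        raise PipelineError("structure thinner than voxel grid")
    return mask


def generate_base_amygdala(spacing=(1.0, 1.0, 1.0),
                           size_params=DEFAULT_AMYGDALA_AXES) -> VolumeMask:
    """Ellipsoid amygdala surrogate; lateral half x > centre, medial x < centre."""
    f, params = base_implicit_field("amygdala", spacing, size_params)
    mask = _mask_from_field(f, spacing, params)
    if mask.n_foreground == 0:
        raise PipelineError("structure thinner than voxel grid")
    return mask


# ---------------------------------------------------------------------------
# ground-truth regions and deformations
# ---------------------------------------------------------------------------

def region_center(params: dict, region: str) -> np.ndarray:
    """Centre (mm, grid-centred coords) of a named region on the base surface."""
    kind = params["kind"]
    a, b, c = (ax / 2.0 for ax in params["axes"])
    bend = params.get("bend", 0.0)
    kappa = _bend_kappa(bend, a) if bend else 0.0
    centers = {
        "hippocampus": {
            "head": (-a, kappa * a ** 2, 0.0),
            "body": (0.0, b, 0.0),
            "tail": (a, kappa * a ** 2, 0.0),
        },
        "amygdala": {
            "lateral": (a, 0.0, 0.0),
            "medial": (-a, 0.0, 0.0),
        },
    }
    try:
        return np.asarray(centers[kind][region], dtype=float)
    except KeyError:
        raise PipelineError(
            f"unknown region {region!r} for structure {kind!r}") from None


def long_axis_t(points_centered: np.ndarray, params: dict) -> np.ndarray:
    """Normalized long-axis coordinate t in [0, 1] for grid-centred points.

    t < 1/3 is the head third, t > 2/3 the tail third (hippocampus); the
    quadratic-shear bend leaves x untouched so t depends on x alone.
    """
    a = params["axes"][0] / 2.0
    return np.clip((np.asarray(points_centered)[..., 0] + a) / (2.0 * a), 0.0, 1.0)


def _bump(shape, spacing, center: np.ndarray, amplitude: float,
          sigma: float) -> np.ndarray:
    X, Y, Z = _centered_coords(shape, spacing)
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    bump = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    bump[d2 > (3.0 * sigma) ** 2] = 0.0  # strictly local support
    return bump.astype(np.float32)


def effect_field(params: dict, effect: EffectSpec,
                 flip_x: bool = False) -> np.ndarray:
    """Inward-displacement field (mm, positive shrinks) for one effect."""
    amp = effect.amplitude
    min_semi = min(params["axes"]) / 2.0
    if amp > min_semi:
        log.warning("effect amplitude %.2f mm exceeds local radius %.2f mm; "
                    "clamping", amp, min_semi)
        amp = min_semi
    center = region_center(params, effect.region)
    if flip_x:
        center = center * np.array([-1.0, 1.0, 1.0])
    return _bump(params["shape"], params["spacing"], center, amp,
                 effect.spatial_sigma)


def apply_regional_deformation(mask: VolumeMask,
                               effect: EffectSpec) -> VolumeMask:
    """Displace the surface inward by a Gaussian bump centred on a region.

    Operates on the implicit field carried in ``mask.meta`` when present
    (exact for generated masks); otherwise a signed distance is recomputed
    from the voxel grid.
    """
    params = mask.meta.get("shape_params")
    if params is None:
        raise PipelineError("mask carries no shape parameters; "
                            "cannot locate the region")
    if effect.structure != params["kind"]:
        raise PipelineError(
            f"effect targets {effect.structure!r} but mask is {params['kind']!r}")
    if effect.amplitude == 0:
        return mask.copy()
    f = mask.meta.get("sdf")
    if f is None:
        inside = mask.grid
        f = (ndimage.distance_transform_edt(~inside, sampling=mask.spacing)
             - ndimage.distance_transform_edt(inside, sampling=mask.spacing)
             ).astype(np.float32)
    f = f + effect_field(params, effect)
    out = _mask_from_field(f, mask.spacing, params)
    out.meta.update({k: v for k, v in mask.meta.items()
                     if k not in ("sdf", "shape_params")})
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

_SEX_P_FEMALE = 0.556       # cohort fraction female
_AGE_MEAN, _AGE_SD = 71.0, 14.0
_AGE_RANGE = (40.0, 95.0)
_TIV_MEAN, _TIV_SD = 1.40e6, 1.2e5   # mm^3
_CDR_LEVELS = (0.5, 1.0, 2.0)
_CDR_P = (0.6, 0.3, 0.1)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _sample_covariates(rng: np.random.Generator, group: str,
                       n: int) -> pd.DataFrame:
    age = _truncated_normal(rng, _AGE_MEAN, _AGE_SD, *_AGE_RANGE, n)
    sex = np.where(rng.random(n) < _SEX_P_FEMALE, "female", "male")
    tiv = rng.normal(_TIV_MEAN, _TIV_SD, n)
    tiv = np.where(sex == "male", tiv * 1.10, tiv)  # males ~10% larger heads
    if group == "HC":
        cdr = np.zeros(n)
        dem = "none"
    else:
        cdr = rng.choice(_CDR_LEVELS, size=n, p=_CDR_P)
        dem = "AD" if group.startswith("AD") else "nonAD"
    field_strength = rng.choice([1.5, 3.0], size=n, p=[0.3, 0.7])
    voxel_volume = rng.choice([0.8, 1.0, 1.2], size=n, p=[0.2, 0.5, 0.3])
    return pd.DataFrame({
        "group": group,
        "age_at_scan": age,
        "sex": sex,
        "tiv": tiv,
        "cdr_global": cdr,
        "field_strength": field_strength,
        "voxel_volume": voxel_volume,
        "dementia_type": dem,
    })


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape, spacing,
                  sigma_mm: float, smooth_mm: float) -> np.ndarray:
    """Spatially smooth surface-displacement noise with std sigma_mm."""
    w = rng.standard_normal(shape).astype(np.float32)
    if sigma_mm == 0:
        return np.zeros(shape, dtype=np.float32)
    sig_vox = [smooth_mm / s for s in spacing]
    w = ndimage.gaussian_filter(w, sig_vox)
    sd = w.std()
    if sd > 0:
        w *= sigma_mm / sd
    return w


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str, str], VolumeMask]]:
    """Generate covariates and paired left/right masks for a full cohort.

    Returns
    -------
    covariates : DataFrame indexed by participant id with columns
        group, age_at_scan, sex, tiv, cdr_global, field_strength,
        voxel_volume, dementia_type.
    masks : dict mapping (participant_id, side, structure) -> VolumeMask.
        Right masks are stored in their native (mirrored) orientation; the
        left mask of a null participant is exactly the sagittal flip of the
        right mask when baseline and noise are zero.
    """
    spacing = config.voxel_spacing
    base: dict[str, tuple[np.ndarray, dict]] = {}
    for structure in config.structures:
        if structure == "hippocampus":
            base[structure] = base_implicit_field(
                "hippocampus", spacing, config.hippocampus_axes, config.bend,
                config.margin_mm)
        elif structure == "amygdala":
            base[structure] = base_implicit_field(
                "amygdala", spacing, config.amygdala_axes, 0.0,
                config.margin_mm)
        else:
            raise ValueError(f"unknown structure {structure!r}")

    # pre-compute per-(structure, group, side) deformation fields
    deform: dict[tuple[str, str, str], np.ndarray] = {}
    for eff in config.effects:
        if eff.structure not in base:
            continue
        f0, params = base[eff.structure]
        # the right structure is generated in the shared canonical (left-like)
        # frame and mirrored afterwards, so effects apply in canonical coords
        bump = effect_field(params, eff)
        for g in eff.affected_groups:
            key = (eff.structure, g, eff.side_shrunk)
            deform[key] = deform.get(key, 0.0) + bump

    rng = np.random.default_rng(config.seed)
    cov_frames = []
    masks: dict[tuple[str, str, str], VolumeMask] = {}
    for group in GROUPS:                       # fixed order => reproducible
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        cov = _sample_covariates(rng, group, n)
        cov.index = [f"{group}_{i:04d}" for i in range(n)]
        cov_frames.append(cov)
        for pid in cov.index:
            for structure in config.structures:
                f0, params = base[structure]
                shape = f0.shape
                noise_l = _smooth_noise(rng, shape, spacing,
                                        config.noise_sigma_mm,
                                        config.noise_smooth_mm)
                noise_r = _smooth_noise(rng, shape, spacing,
                                        config.noise_sigma_mm,
                                        config.noise_smooth_mm)
                f_left = f0 + config.baseline_asym_mm + noise_l
                f_right = f0 + noise_r
                for side in ("left", "right"):
                    key = (structure, group, side)
                    if key in deform:
                        if side == "left":
                            f_left = f_left + deform[key]
                        else:
                            f_right = f_right + deform[key]
                ml = _mask_from_field(f_left, spacing, params)
                # mirror the right structure into its native orientation
                mr = VolumeMask((f_right < 0)[::-1, :, :].copy(), spacing,
                                meta={"shape_params": params,
                                      "mirrored": True})
                for m, side in ((ml, "left"), (mr, "right")):
                    m.meta.update(participant=pid, side=side,
                                  structure=structure, group=group)
                ml.meta.pop("sdf", None)       # keep cohorts lightweight
                masks[(pid, "left", structure)] = ml
                masks[(pid, "right", structure)] = mr
    covariates = pd.concat(cov_frames)
    covariates.index.name = "participant_id"
    return covariates, masks


def null_config(**overrides) -> CohortConfig:
    """A no-effect cohort config (convenience for null simulations)."""
    defaults = dict(baseline_asym_mm=0.0, noise_sigma_mm=0.0, effects=())
    defaults.update(overrides)
    return CohortConfig(**defaults)


def with_effects(config: CohortConfig, *effects: EffectSpec) -> CohortConfig:
    return replace(config, effects=tuple(config.effects) + tuple(effects))
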