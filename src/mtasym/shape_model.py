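"""Mirrored correspondence-point shape model.

Right-hemisphere shapes are reflected across the sagittal (left-right) axis
so that both hemispheres live in one shape space.  All shapes are then
rigidly aligned (rotation + translation only -- size differences are real
signal here and are adjusted for statistically, not normalized away), a
template surface is extracted from the voxel-wise mean signed-distance
field, M near-uniform template points are chosen by farthest-point
sampling, and each template point is projected onto every subject's surface
along the template normal.  Point k therefore refers to the same template
location on every subject and side, which is what makes point-wise
statistics across participants meaningful.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from skimage import measure

from .types import (DistanceField, PipelineError, RigidTransform, ShapeModel)

log = logging.getLogger(__name__)

DEFAULT_SEARCH_RADIUS = 10.0   # mm, +/- along the normal
FALLBACK_QC_FRACTION = 0.05


# ---------------------------------------------------------------------------
# reflection
# ---------------------------------------------------------------------------

def flip_sagittal(field: DistanceField) -> DistanceField:
    """Reflect the x (left-right) axis about the grid centre.

    An exact involution: flipping twice returns the original voxel data.
    """
    if field.orientation != "RAS":
        raise PipelineError(
            f"unknown orientation {field.orientation!r}; expected RAS")
    out = field.copy()
    out.grid = field.grid[::-1, :, :].copy()
    out.meta["sagittal_flipped"] = not field.meta.get("sagittal_flipped", False)
    return out


# ---------------------------------------------------------------------------
# surfaces and alignment
# ---------------------------------------------------------------------------

def surface_points(field: DistanceField, max_points: int | None = None
                   ) -> np.ndarray:
    """Zero-level-set vertices (world mm) via marching cubes."""
    grid = np.asarray(field.grid, dtype=np.float32)
    if (grid >= 0).all() or (grid <= 0).all():
        raise PipelineError("field has no zero level set")
    verts, _, _, _ = measure.marching_cubes(grid, level=0.0,
                                            spacing=field.spacing)
    verts = verts + np.asarray(field.origin)
    if max_points is not None and len(verts) > max_points:
        stride = int(np.ceil(len(verts) / max_points))
        verts = verts[::stride]
    return np.ascontiguousarray(verts, dtype=np.float64)


def align_rigid(fields: list[DistanceField],
                reference: int = 0,
                tol: float = 1e-3,
                max_iter: int = 100,
                max_points: int = 500) -> list[RigidTransform]:
    """Rigid (rotation + translation) alignment of all shapes to a common frame.

    Iterative closest-surface Procrustes against the reference shape: each
    moved surface point is matched to its foot point on the reference
    surface (projected through the reference signed-distance field and its
    gradient), the pose is updated by the Kabsch solution, and the sweep is
    iterated until the mean point movement falls below ``tol`` mm (or
    ``max_iter`` sweeps, with a warning).  Projection through the distance
    field avoids the tangential sliding of nearest-neighbour matching on
    smooth shapes.  Scaling is deliberately excluded so that genuine size
    differences survive into the asymmetry statistic.

    All shapes are swept simultaneously (one field lookup and one batched
    Kabsch solve per sweep); each shape keeps iterating until its own
    movement criterion is met.
    """
    if len(fields) < 2:
        raise PipelineError("alignment requires at least 2 shapes")
    clouds = [surface_points(f, max_points) for f in fields]
    ref_field = fields[reference]
    ref_grads = np.gradient(ref_field.grid, *ref_field.spacing)
    ref_centroid = clouds[reference].mean(axis=0)

    def project_to_ref(pts: np.ndarray) -> np.ndarray:
        val = _sample_field(ref_field, pts)
        g = np.stack([_sample_grid(gr, ref_field, pts) for gr in ref_grads],
                     axis=1)
        g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-9)
        return pts - val[:, None] * g

    n = len(clouds)
    R = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    t = np.stack([ref_centroid - c.mean(axis=0) for c in clouds])
    prev = [c + ti for c, ti in zip(clouds, t)]
    done = np.zeros(n, dtype=bool)
    # geometric extrapolation state (Besl-McKay style): last pose step
    d_prev = np.zeros((n, 6))
    d_valid = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        active = np.flatnonzero(~done)
        if not len(active):
            break
        sizes = np.array([len(clouds[i]) for i in active])
        offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
        src = np.vstack([clouds[i] for i in active])
        aid = np.repeat(np.arange(len(active)), sizes)
        mu_s = np.add.reduceat(src, offsets, axis=0) / sizes[:, None]
        moved = np.einsum("nij,nj->ni", R[active][aid], src) + t[active][aid]
        dst = project_to_ref(moved)
        # per-cloud Kabsch: H_i = sum (src - mu_s)(dst - mu_d)^T
        mu_d = np.add.reduceat(dst, offsets, axis=0) / sizes[:, None]
        cross = np.add.reduceat(src[:, :, None] * dst[:, None, :],
                                offsets, axis=0)
        H = cross - sizes[:, None, None] * (mu_s[:, :, None]
                                            * mu_d[:, None, :])
        U, _, Vt = np.linalg.svd(H)
        det = np.linalg.det(np.einsum("nij,nkj->nik",
                                      Vt.transpose(0, 2, 1), U))
        D = np.broadcast_to(np.eye(3), (len(active), 3, 3)).copy()
        D[:, 2, 2] = np.sign(det)
        R_new = np.einsum("nji,njk,nlk->nil", Vt, D, U)
        t_new = mu_d - np.einsum("nij,nj->ni", R_new, mu_s)
        # pose step in se(3); extrapolate along a consistent step direction
        # (ICP converges geometrically, so summing the series jumps ahead)
        rv = Rotation.from_matrix(
            np.einsum("nij,nkj->nik", R_new, R[active])).as_rotvec()
        dv = np.concatenate([rv, t_new - t[active]], axis=1)
        n1 = np.linalg.norm(dv, axis=1)
        n0 = np.linalg.norm(d_prev[active], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosang = np.einsum("ni,ni->n", d_prev[active], dv) / (n0 * n1)
            rho = n1 / n0
        ok = d_valid[active] & (n0 > 0) & (n1 > 0) & (cosang > 0.9) & (rho < 1)
        if ok.any():
            gamma = np.minimum(rho[ok] / (1.0 - rho[ok]), 15.0)
            R_new[ok] = np.einsum(
                "nij,njk->nik",
                Rotation.from_rotvec(rv[ok] * gamma[:, None]).as_matrix(),
                R_new[ok])
            t_new[ok] = t_new[ok] + (t_new[ok] - t[active][ok]) * gamma[:, None]
        d_prev[active] = dv
        d_valid[active] = ~ok          # no back-to-back extrapolation
        R[active] = R_new
        t[active] = t_new
        new = np.einsum("nij,nj->ni", R[active][aid], src) + t[active][aid]
        for a, i in enumerate(active):
            sl = slice(offsets[a], offsets[a] + sizes[a])
            if np.abs(new[sl] - prev[i]).mean() < tol:
                done[i] = True
            prev[i] = new[sl]
    if not done.all():
        warnings.warn(f"rigid alignment did not converge for "
                      f"{int((~done).sum())} shape(s); using best iterates")
    return [RigidTransform(R[i], t[i]) for i in range(n)]


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _sample_field(field: DistanceField, points: np.ndarray) -> np.ndarray:
    """Trilinear samples of the field at world-coordinate points."""
    idx = (points - np.asarray(field.origin)) / np.asarray(field.spacing)
    return ndimage.map_coordinates(field.grid, idx.T, order=1, mode="nearest")


def _sample_grid(grid: np.ndarray, like: DistanceField,
                 points: np.ndarray) -> np.ndarray:
    """Sample an arbitrary array living on the same grid as ``like``."""
    idx = (points - np.asarray(like.origin)) / np.asarray(like.spacing)
    return ndimage.map_coordinates(grid, idx.T, order=1, mode="nearest")


def mean_distance_field(fields: list[DistanceField],
                        transforms: list[RigidTransform],
                        reference: int = 0) -> DistanceField:
    """Voxel-wise mean of the aligned signed-distance fields.

    Each field is sampled on the reference shape's grid through its rigid
    transform, so no field is ever resampled onto disk.
    """
    ref = fields[reference]
    xs, ys, zs = ref.world_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    acc = np.zeros(pts.shape[0], dtype=np.float64)
    for f, T in zip(fields, transforms):
        acc += _sample_field(f, T.invert(pts))
    mean = (acc / len(fields)).reshape(ref.grid.shape).astype(np.float32)
    return DistanceField(mean, ref.spacing, ref.origin,
                         meta={"n_shapes": len(fields)})


def build_template(mean_field: DistanceField) -> tuple[np.ndarray, np.ndarray]:
    """Iso-surface (level 0) of the mean field as a triangle mesh.

    Returns (vertices, faces); vertices are world coordinates in mm.
    """
    grid = mean_field.grid
    if (grid >= 0).all() or (grid <= 0).all():
        raise PipelineError("mean field is single-phase; no template surface")
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.0,
                                                spacing=mean_field.spacing)
    verts = verts + np.asarray(mean_field.origin)
    return np.ascontiguousarray(verts), faces


def farthest_point_sample(mesh_vertices: np.ndarray, M: int) -> np.ndarray:
    """Greedy farthest-point subset of M vertex indices, fully deterministic.

    Starts at the lexicographically smallest vertex; each subsequent pick
    maximizes the minimum distance to the chosen set, ties broken by lowest
    index.  Yields near-uniform surface coverage.
    """
    verts = np.asarray(mesh_vertices, dtype=np.float64)
    N = len(verts)
    if N < M:
        raise PipelineError(f"cannot sample {M} points from {N} vertices")
    start = int(np.lexsort((verts[:, 2], verts[:, 1], verts[:, 0]))[0])
    chosen = np.empty(M, dtype=np.intp)
    chosen[0] = start
    d2 = np.sum((verts - verts[start]) ** 2, axis=1)
    for i in range(1, M):
        nxt = int(np.argmax(d2))         # argmax takes the lowest tied index
        chosen[i] = nxt
        d2 = np.minimum(d2, np.sum((verts - verts[nxt]) ** 2, axis=1))
    return chosen


def template_normals(mean_field: DistanceField,
                     template_points: np.ndarray) -> np.ndarray:
    """Outward unit normals: normalized positive gradient of the mean field."""
    grads = np.gradient(mean_field.grid.astype(np.float64),
                        *mean_field.spacing)
    idx = ((template_points - np.asarray(mean_field.origin))
           / np.asarray(mean_field.spacing))
    g = np.stack([ndimage.map_coordinates(gr, idx.T, order=1, mode="nearest")
                  for gr in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    if (norms < 1e-9).any():
        raise PipelineError("zero gradient at a template point; "
                            "cannot define an outward normal")
    return g / norms[:, None]


# ---------------------------------------------------------------------------
# correspondence by normal-line projection
# ---------------------------------------------------------------------------

def correspond(template_points: np.ndarray,
               template_normals_arr: np.ndarray,
               subject_field: DistanceField,
               transform: RigidTransform | None = None,
               search_radius: float = DEFAULT_SEARCH_RADIUS,
               step: float | None = None) -> tuple[np.ndarray, int]:
    """Project template points onto a subject surface along template normals.

    For each template point the subject's signed distance is sampled along
    the normal line within +/- ``search_radius`` mm and the zero crossing
    nearest the template point is taken (linearly interpolated).  Points
    with no crossing fall back to the globally nearest surface vertex and
    are counted; a high fallback fraction flags the subject for QC.

    Returns (M x 3 corresponded points in the template frame, n_fallback).
    """
    if transform is None:
        transform = RigidTransform.identity()
    M = len(template_points)
    if step is None:
        step = 0.25 * min(subject_field.spacing)
    s = np.arange(-search_radius, search_radius + step / 2, step)
    lines = (template_points[:, None, :]
             + s[None, :, None] * template_normals_arr[:, None, :])
    vals = _sample_field(subject_field,
                         transform.invert(lines.reshape(-1, 3))).reshape(M, -1)

    sign_change = vals[:, :-1] * vals[:, 1:] <= 0
    # exclude intervals where both endpoints are exactly zero far off-surface
    sign_change &= ~((vals[:, :-1] == 0) & (vals[:, 1:] == 0))
    mid = 0.5 * (s[:-1] + s[1:])
    dist_mid = np.where(sign_change, np.abs(mid)[None, :], np.inf)
    best = np.argmin(dist_mid, axis=1)
    has_crossing = np.isfinite(dist_mid[np.arange(M), best])

    v0 = vals[np.arange(M), best]
    v1 = vals[np.arange(M), best + 1]
    denom = np.where(np.abs(v1 - v0) < 1e-12, 1.0, v1 - v0)
    frac = np.clip(-v0 / denom, 0.0, 1.0)
    s_star = s[best] + frac * step
    points = template_points + s_star[:, None] * template_normals_arr

    n_fallback = int((~has_crossing).sum())
    if n_fallback:
        surf = transform.apply(surface_points(subject_field))
        tree = cKDTree(surf)
        _, nn = tree.query(template_points[~has_crossing])
        points[~has_crossing] = surf[nn]
        log.info("correspondence fell back to nearest surface point for "
                 "%d/%d template points", n_fallback, M)
    return points, n_fallback


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_shape_model(fields: dict[tuple[str, str], DistanceField],
                      structure: str,
                      n_points: int,
                      search_radius: float = DEFAULT_SEARCH_RADIUS,
                      align_max_points: int = 500) -> ShapeModel:
    """Build the full mirrored correspondence model for one structure.

    ``fields`` maps (participant_id, side) with side in
    {"left", "right_flipped"} to groomed distance fields; right-hemisphere
    fields must already be sagittally flipped.
    """
    keys = sorted(fields.keys())
    if len(keys) < 2:
        raise PipelineError("shape model requires at least 2 shapes")
    field_list = [fields[k] for k in keys]
    transforms = align_rigid(field_list, max_points=align_max_points)
    mean_f = mean_distance_field(field_list, transforms)
    verts, faces = build_template(mean_f)
    sel = farthest_point_sample(verts, n_points)
    tpl_points = verts[sel]
    tpl_normals = template_normals(mean_f, tpl_points)

    subject_points: dict[tuple[str, str], np.ndarray] = {}
    fallback: dict[tuple[str, str], float] = {}
    for key, T in zip(keys, transforms):
        pts, n_fb = correspond(tpl_points, tpl_normals, fields[key], T,
                               search_radius)
        subject_points[key] = pts
        frac = n_fb / n_points
        fallback[key] = frac
        if frac > FALLBACK_QC_FRACTION:
            warnings.warn(f"subject {key} used fallback correspondence for "
                          f"{frac:.1%} of points; flagged for QC")
    return ShapeModel(structure=structure, n_points=n_points,
                      template_points=tpl_points,
                      template_normals=tpl_normals,
                      template_mesh=(verts, faces),
                      subject_points=subject_points,
                      transforms=dict(zip(keys, transforms)),
                      fallback_fraction=fallback,
                      mean_field=mean_f)
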