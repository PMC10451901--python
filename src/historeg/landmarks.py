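"""Step 1 of the workflow: fiducial-landmark registration of each digitized
whole-mount section to its ex vivo MRI slice, and embedding of the result
into the ex vivo 3D grid.

The estimator solves the classical similarity Procrustes problem in closed
form (centroid alignment + SVD of the cross-covariance, reflection
corrected, uniform scale from the variance ratio) — the "rigid + uniform
scale" transform used to pin each section onto the fiducial holes of its
ex vivo slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AffineTransform, LandmarkSet, Transform, Volume
from .io import HistologySlice

__all__ = [
    "LandmarkFit",
    "estimate_similarity",
    "estimate_affine",
    "find_corresponding_slice",
    "embed_slice",
]


@dataclass
class LandmarkFit:
    """A fitted point-based transform together with its goodness of fit.

    ``transform`` maps moving-space points onto fixed-space points (the
    least-squares direction); ``transform.inverse()`` is the pull-back used
    for resampling.  ``residual_rms`` is the root-mean-square fiducial
    registration error in mm.
    """

    transform: AffineTransform
    residual_rms: float


def _check_configuration(points: np.ndarray, min_points: int) -> None:
    n, d = points.shape
    if n < min_points:
        raise ValueError(f"need at least {min_points} point pairs, got {n}")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # collinear (2D) / collinear-or-worse (3D): second singular value vanishes
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate landmark configuration (collinear points)")


def estimate_similarity(
    fixed: LandmarkSet, moving: LandmarkSet, allow_scale: bool = True
) -> LandmarkFit:
    """Closed-form least-squares rigid(+uniform scale) fit of paired points.

    Minimizes sum_i ||fixed_i - S(moving_i)||^2 over rotations R, translations
    t and (optionally) a single scale s, with the reflection-corrected SVD
    solution; works in 2D and 3D.  With ``allow_scale=False`` the result is a
    proper rotation (det = +1) plus translation.
    """
    fixed.check_paired(moving)
    if fixed.dim != moving.dim:
        raise ValueError("fixed and moving landmark dimensionality differ")
    x = moving.points
    y = fixed.points
    _check_configuration(x, 3)
    _check_configuration(y, 3)
    mu_x = x.mean(axis=0)
    mu_y = y.mean(axis=0)
    xc = x - mu_x
    yc = y - mu_y
    cov = yc.T @ xc / len(x)
    u, s, vt = np.linalg.svd(cov)
    d = fixed.dim
    sign = np.sign(np.linalg.det(u @ vt))
    corr = np.ones(d)
    corr[-1] = sign if sign != 0 else 1.0
    rot = u @ np.diag(corr) @ vt
    if allow_scale:
        var_x = (xc**2).sum() / len(x)
        scale = float((s * corr).sum() / var_x)
        if scale <= 0:
            raise ValueError("degenerate configuration: non-positive scale")
    else:
        scale = 1.0
    matrix = scale * rot
    trans = mu_y - matrix @ mu_x
    kind = "similarity" if allow_scale else "rigid"
    transform = AffineTransform(matrix, trans, kind=kind)
    residual = transform(x) - y
    rms = float(np.sqrt((residual**2).sum() / len(x)))
    return LandmarkFit(transform, rms)


def estimate_affine(fixed: LandmarkSet, moving: LandmarkSet) -> LandmarkFit:
    """Full least-squares affine fit of paired points (2D: ≥3 non-collinear;
    3D: ≥4 in general position)."""
    fixed.check_paired(moving)
    d = fixed.dim
    x = moving.points
    y = fixed.points
    _check_configuration(x, d + 1)
    design = np.hstack([x, np.ones((len(x), 1))])
    if np.linalg.matrix_rank(design) < d + 1:
        raise ValueError("rank-deficient landmark design (degenerate configuration)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    matrix = coef[:d].T
    trans = coef[d]
    transform = AffineTransform(matrix, trans, kind="affine")
    residual = transform(x) - y
    rms = float(np.sqrt((residual**2).sum() / len(x)))
    return LandmarkFit(transform, rms)


def find_corresponding_slice(
    histology_landmarks: LandmarkSet,
    exvivo_landmarks_by_index: dict[int, LandmarkSet],
    search_range: tuple[int, int] | None = None,
) -> tuple[int, float]:
    """Find the ex vivo axial slice a section was cut from.

    For each candidate slice the section's fiducial landmarks are registered
    (similarity) to that slice's fiducial points; the candidate with the
    lowest residual RMS wins (ties break to the lowest index).  Returns
    ``(index, residual_rms)``.
    """
    candidates = sorted(exvivo_landmarks_by_index)
    if search_range is not None:
        lo, hi = search_range
        candidates = [k for k in candidates if lo <= k <= hi]
    if not candidates:
        raise ValueError("empty slice search range")
    best: tuple[int, float] | None = None
    for k in candidates:
        fit = estimate_similarity(exvivo_landmarks_by_index[k], histology_landmarks)
        if best is None or fit.residual_rms < best[1] - 1e-12:
            best = (k, fit.residual_rms)
    assert best is not None
    return best


def embed_slice(
    slice_: HistologySlice,
    pullback: Transform,
    reference: Volume,
    index: int,
    channel: str = "image",
) -> Volume:
    """Embed a registered section into a volume with the ex vivo geometry.

    ``pullback`` maps ex vivo in-plane world points (x, y) of axial slice
    ``index`` into the section's own 2D world frame.  All other slices are
    zero-filled; the section image is sampled linearly, the annotation with
    nearest neighbours.
    """
    nx, ny, nz = reference.shape
    if not 0 <= index < nz:
        raise IndexError(f"axial index {index} outside [0, {nz})")
    if channel not in ("image", "annotation"):
        raise ValueError("channel must be 'image' or 'annotation'")
    data = slice_.image if channel == "image" else slice_.annotation.astype(float)
    order = 1 if channel == "image" else 0

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    idx3 = np.stack([ii, jj, np.full_like(ii, index)], axis=-1).reshape(-1, 3).astype(float)
    world = reference.voxel_to_world(idx3)
    histo_world = pullback(world[:, :2])
    histo_px = slice_.world_to_pixel(histo_world)
    values = ndimage.map_coordinates(
        data, histo_px.T, order=order, mode="constant", cval=0.0, prefilter=False
    )
    voxels = np.zeros(reference.shape)
    voxels[:, :, index] = values.reshape(nx, ny)
    if channel == "annotation":
        voxels = (voxels > 0.5).astype(np.uint8)
    return reference.geometry_like(voxels)
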