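"""Multiscale optical-flow deformable registration.

Each moving frame is registered to the reference (first) frame with a
variational intensity-conservation flow of the Horn–Schunck family:
the data term penalises the linearised brightness-constancy residual and a
quadratic smoothness term penalises the field gradient.  The flow is
solved coarse-to-fine on a Gaussian pyramid (three levels, factor 2), with
the moving image re-warped by the current estimate between inner solves so
displacements beyond the linearisation range are captured incrementally.

Following the intended use — building smooth displacement fields for a
motion model rather than maximising per-voxel sharpness — the optimisation
stops at half the original resolution and the final field is linearly
upsampled to the full grid, which acts as an additional smoothing step.

All fields are expressed in millimetres on the fixed grid (anisotropic
voxels are handled by taking image gradients and the smoothness stencil in
physical units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from .core import DisplacementField, ImageVolume

__all__ = ["RegistrationParams", "register", "register_series"]


@dataclass(frozen=True)
class RegistrationParams:
    """Controls for the multiscale optical-flow solver.

    ``regularization_weight`` is the Horn–Schunck alpha for images
    normalised to unit intensity range, in intensity-per-mm units: larger
    values give smoother, smaller-magnitude fields.
    ``stop_level_downsample`` sets the finest level actually optimised;
    with the default 2 the full-resolution level is never solved, only
    interpolated.
    """

    pyramid_levels: int = 3
    downsample_factor: int = 2
    stop_level_downsample: int = 2
    regularization_weight: float = 0.015
    iterations_per_level: int = 160
    warps_per_level: int = 8
    field_smoothing_sigma_vox: float = 1.0
    convergence_tol_mm: float = 1e-3

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.downsample_factor < 2:
            raise ValueError("downsample_factor must be >= 2")
        if self.regularization_weight <= 0:
            raise ValueError("regularization_weight must be positive")
        # stop level must be a power of the factor
        level = self.stop_level_downsample
        while level > 1 and level % self.downsample_factor == 0:
            level //= self.downsample_factor
        if level != 1:
            raise ValueError(
                "stop_level_downsample must be a power of downsample_factor"
            )


def _downsample(vol: np.ndarray, factor: int) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(vol, sigma=factor / 2.0, mode="nearest")
    return smoothed[tuple(slice(None, None, factor) for _ in range(3))]


def _upsample_field(field: np.ndarray, target_shape) -> np.ndarray:
    """Linearly interpolate a (nx,ny,nz,3) mm field onto a finer grid."""
    zoom = [t / s for t, s in zip(target_shape, field.shape[:3])]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = ndimage.zoom(
            field[..., c], zoom, order=1, mode="nearest", grid_mode=True
        )
    return out


def _neighbor_mean(vol: np.ndarray, inv_h2: np.ndarray) -> np.ndarray:
    """Spacing-weighted 6-neighbour average (edge-replicated)."""
    total = np.zeros_like(vol)
    for axis in range(3):
        padded = np.pad(
            vol, [(1, 1) if a == axis else (0, 0) for a in range(3)], mode="edge"
        )
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        total += inv_h2[axis] * (padded[tuple(lo)] + padded[tuple(hi)])
    return total / (2.0 * inv_h2.sum())


def _warp_same_grid(vol: np.ndarray, field_mm: np.ndarray, spacing) -> np.ndarray:
    coords = np.array(
        np.meshgrid(*[np.arange(n, dtype=float) for n in vol.shape], indexing="ij")
    )
    coords += np.moveaxis(field_mm / np.asarray(spacing), -1, 0)
    return ndimage.map_coordinates(vol, coords, order=1, mode="nearest")


def _solve_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing: np.ndarray,
    field: np.ndarray,
    params: RegistrationParams,
) -> np.ndarray:
    """Incremental Horn–Schunck at one pyramid level, warm-started."""
    inv_h2 = 1.0 / spacing**2
    kappa = 2.0 * inv_h2.sum()
    alpha2 = params.regularization_weight**2
    inner = max(params.iterations_per_level // params.warps_per_level, 1)
    for _ in range(params.warps_per_level):
        warped = _warp_same_grid(moving, field, spacing)
        it = warped - fixed
        grads = np.stack(
            np.gradient(0.5 * (warped + fixed), *spacing), axis=-1
        )
        g2 = np.sum(grads * grads, axis=-1)
        denom = alpha2 * kappa + g2
        delta = np.zeros_like(field)
        for _ in range(inner):
            dbar = np.stack(
                [_neighbor_mean(delta[..., c], inv_h2) for c in range(3)],
                axis=-1,
            )
            residual = np.sum(grads * dbar, axis=-1) + it
            delta = dbar - grads * (residual / denom)[..., None]
        step = float(np.max(np.linalg.norm(delta, axis=-1)))
        field = field + delta
        # Gaussian smoothing of the accumulated field keeps incremental
        # updates from random-walking on image noise across warps
        sigma = params.field_smoothing_sigma_vox
        if sigma > 0:
            for c in range(3):
                field[..., c] = ndimage.gaussian_filter(
                    field[..., c], sigma, mode="nearest"
                )
        if step < params.convergence_tol_mm:
            break
    return field


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: RegistrationParams = RegistrationParams(),
) -> DisplacementField:
    """Estimate the displacement field mapping the fixed (reference) grid
    into the moving frame, so that resampling the moving image at
    ``r + d(r)`` aligns it with the fixed image."""
    if not fixed.same_grid(moving):
        raise ValueError(
            f"grid mismatch: fixed {fixed.shape} @ {fixed.spacing_mm} vs "
            f"moving {moving.shape} @ {moving.spacing_mm}"
        )
    lo = min(fixed.voxels.min(), moving.voxels.min())
    hi = max(fixed.voxels.max(), moving.voxels.max())
    if hi - lo < 1e-12:
        warnings.warn(
            "constant images carry no intensity gradient; returning zero field"
        )
        return DisplacementField.zeros_like(fixed)
    f_norm = (fixed.voxels - lo) / (hi - lo)
    m_norm = (moving.voxels - lo) / (hi - lo)

    factor = params.downsample_factor
    stop_level = round(
        np.log(params.stop_level_downsample) / np.log(factor)
    ) if params.stop_level_downsample > 1 else 0

    # pyramid[level] = (fixed, moving, spacing); level 0 is full resolution
    pyramid = [(f_norm, m_norm, np.asarray(fixed.spacing_mm, dtype=float))]
    for _ in range(params.pyramid_levels - 1):
        f_prev, m_prev, sp = pyramid[-1]
        pyramid.append(
            (_downsample(f_prev, factor), _downsample(m_prev, factor), sp * factor)
        )

    field = np.zeros(pyramid[-1][0].shape + (3,))
    for level in range(params.pyramid_levels - 1, stop_level - 1, -1):
        f_l, m_l, sp_l = pyramid[level]
        if field.shape[:3] != f_l.shape:
            field = _upsample_field(field, f_l.shape)
        field = _solve_level(f_l, m_l, sp_l, field, params)
    if field.shape[:3] != fixed.shape:
        field = _upsample_field(field, fixed.shape)
    return DisplacementField(
        field, spacing_mm=fixed.spacing_mm, origin_mm=fixed.origin_mm
    )


def register_series(
    frames: List[ImageVolume],
    params: RegistrationParams = RegistrationParams(),
) -> List[DisplacementField]:
    """Register every frame to the first (reference) frame.

    Returns one field per frame; frame 0's field is identically zero by
    construction.
    """
    if len(frames) < 2:
        raise ValueError(f"need at least 2 frames, got {len(frames)}")
    fields = [DisplacementField.zeros_like(frames[0])]
    for frame in frames[1:]:
        fields.append(register(frames[0], frame, params))
    return fields
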