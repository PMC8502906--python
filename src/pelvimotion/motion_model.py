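"""Boundary-voxel PCA motion model of displacement vector fields.

The model decomposes a training set of displacement fields, sampled only
at the segmentation-boundary voxels of the reference frame, into a mean
displacement and orthonormal principal components ranked by explained
variance.  Restricting to the boundary captures the organ motion while
discarding the less reliable registration output inside large homogeneous
organs (e.g. the bladder lumen).

Given a new displacement field ``x``, the model approximation with ``k``
components is

    x_model = x_mean + sum_{n<=k} w_n * PC_n,     ||PC_n|| = 1,

where the optimal weights are the projections of the centred field onto
the components, ``w_n = (x - x_mean) . PC_n``.  The per-voxel residual
``eps_i = ||x_model - x_ref||_i`` (mm) measures the motion the model does
not explain.

Vectors over the ``N`` boundary voxels are stacked voxel-major with the
``(x, y, z)`` components innermost, giving 3N-dimensional observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .core import DisplacementField, LabelMaskSet
from .metrics import boundary_voxels

__all__ = [
    "BoundaryIndexSet",
    "MotionModel",
    "ModelFit",
    "extract_boundary",
    "build_model",
    "reconstruct",
    "optimal_weights",
    "residuals",
    "fit_field",
    "cumulative_variance",
]

# components with eigenvalue below this fraction of the largest are noise rank
_EIGENVALUE_CUTOFF = 1e-12


@dataclass(frozen=True)
class BoundaryIndexSet:
    """Ordered voxel indices on the reference segmentation boundary."""

    indices: np.ndarray  # (N, 3) int, lexicographically ordered
    grid_shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float]

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError(f"indices must be (N, 3), got {idx.shape}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def sample(self, field: DisplacementField) -> np.ndarray:
        """Stack a field's boundary values into a 3N vector (mm)."""
        if field.shape != tuple(self.grid_shape):
            raise ValueError(
                f"grid mismatch: field {field.shape} vs boundary grid "
                f"{tuple(self.grid_shape)}"
            )
        i, j, k = self.indices.T
        return field.vectors[i, j, k].ravel()


def extract_boundary(masks: LabelMaskSet, scope: str = "joint") -> BoundaryIndexSet:
    """Boundary voxels (6-connectivity) of the reference segmentation.

    ``scope`` is ``"joint"`` — the union of the per-organ boundaries, the
    support of the combined model — or an organ name for a per-organ set.
    """
    if scope == "joint":
        bound = np.zeros(masks.shape, dtype=bool)
        for _, mask in masks.items():
            if not mask.any():
                raise ValueError("cannot extract boundary of an empty mask")
            bound |= boundary_voxels(mask)
    else:
        mask = masks[scope]
        if not mask.any():
            raise ValueError(f"mask '{scope}' is empty")
        bound = boundary_voxels(mask)
    return BoundaryIndexSet(
        indices=np.argwhere(bound),
        grid_shape=masks.shape,
        spacing_mm=masks.spacing_mm,
    )


@dataclass(frozen=True)
class MotionModel:
    """PCA motion model on a fixed reference-boundary index set.

    ``components`` rows are unit-norm over the stacked 3N vector and
    mutually orthogonal; ``eigenvalues`` (mm², descending) are the sample
    variances of the training coefficients along each component.
    """

    boundary: BoundaryIndexSet
    mean_displacement: np.ndarray  # (3N,), mm
    components: np.ndarray  # (n_components, 3N), rows unit norm
    eigenvalues: np.ndarray  # (n_components,), descending
    n_training: int

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def save(self, path) -> None:
        """Serialize to a single .npz archive (versioned layout)."""
        np.savez(
            path,
            format_version=1,
            boundary_indices=self.boundary.indices,
            grid_shape=np.asarray(self.boundary.grid_shape),
            spacing_mm=np.asarray(self.boundary.spacing_mm),
            mean_displacement=self.mean_displacement,
            components=self.components,
            eigenvalues=self.eigenvalues,
            n_training=self.n_training,
        )

    @classmethod
    def load(cls, path) -> "MotionModel":
        with np.load(path) as data:
            if int(data["format_version"]) != 1:
                raise ValueError(
                    f"unsupported model format version {data['format_version']}"
                )
            boundary = BoundaryIndexSet(
                indices=data["boundary_indices"],
                grid_shape=tuple(int(n) for n in data["grid_shape"]),
                spacing_mm=tuple(float(s) for s in data["spacing_mm"]),
            )
            return cls(
                boundary=boundary,
                mean_displacement=data["mean_displacement"],
                components=data["components"],
                eigenvalues=data["eigenvalues"],
                n_training=int(data["n_training"]),
            )


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting the model to one displacement field."""

    weights: np.ndarray  # (k,)
    residuals: np.ndarray  # (N,), mm, >= 0
    n_components_used: int

    @property
    def mean_residual(self) -> float:
        return float(self.residuals.mean())


def build_model(
    training_fields: Sequence[DisplacementField], boundary: BoundaryIndexSet
) -> MotionModel:
    """PCA of the training fields sampled at the boundary voxels.

    Uses the SVD of the centred observation matrix (observations are the
    stacked 3N boundary vectors of each training field); eigenvalues are
    those of the sample covariance (denominator ``n - 1``).  Components
    with eigenvalue below numerical rank are dropped; each retained
    component's sign is fixed so its first nonzero entry is positive.
    """
    if len(training_fields) < 2:
        raise ValueError(
            f"need at least 2 training fields, got {len(training_fields)}"
        )
    if len(boundary) == 0:
        raise ValueError("boundary index set is empty")
    obs = np.stack([boundary.sample(f) for f in training_fields])
    mean = obs.mean(axis=0)
    centred = obs - mean
    # SVD route: avoids forming the 3N x 3N covariance
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = svals**2 / (len(training_fields) - 1)
    # numerical-rank floor: relative to the spectrum, but never below the
    # rounding noise of the observations themselves (identical training
    # fields must yield an empty spectrum, not a 1e-30 component)
    floor = _EIGENVALUE_CUTOFF * max(
        eigenvalues[0] if len(eigenvalues) else 0.0, float(np.mean(obs**2))
    )
    keep = eigenvalues > floor
    components = vt[keep]
    eigenvalues = eigenvalues[keep]
    for row in components:  # deterministic sign: first nonzero entry > 0
        nz = np.flatnonzero(np.abs(row) > 1e-14)
        if len(nz) and row[nz[0]] < 0:
            row *= -1.0
    return MotionModel(
        boundary=boundary,
        mean_displacement=mean,
        components=components,
        eigenvalues=eigenvalues,
        n_training=len(training_fields),
    )


def reconstruct(
    model: MotionModel, weights: Sequence[float], k: "int | None" = None
) -> np.ndarray:
    """Model displacement at the boundary: mean + weighted components (mm)."""
    weights = np.asarray(weights, dtype=float)
    if k is None:
        k = len(weights)
    if k > model.n_components:
        raise ValueError(
            f"k={k} exceeds the {model.n_components} stored components"
        )
    if len(weights) < k:
        raise ValueError(f"got {len(weights)} weights for k={k}")
    out = model.mean_displacement.copy()
    if k:
        out += weights[:k] @ model.components[:k]
    return out


def optimal_weights(
    model: MotionModel, field: DisplacementField, k: "int | None" = None
) -> np.ndarray:
    """Least-squares optimal weights: projection of the centred field onto
    each of the first ``k`` components."""
    if k is None:
        k = model.n_components
    if k > model.n_components:
        raise ValueError(
            f"k={k} exceeds the {model.n_components} stored components"
        )
    centred = model.boundary.sample(field) - model.mean_displacement
    return model.components[:k] @ centred


def residuals(
    model_field: np.ndarray,
    reference_field: "DisplacementField | np.ndarray",
    boundary: BoundaryIndexSet,
    squared: bool = False,
) -> np.ndarray:
    """Per-boundary-voxel residual: Euclidean norm (mm) of the difference
    between the model and reference displacement.  ``squared=True`` returns
    the squared norm instead."""
    if isinstance(reference_field, DisplacementField):
        ref = boundary.sample(reference_field)
    else:
        ref = np.asarray(reference_field, dtype=float).ravel()
    model_field = np.asarray(model_field, dtype=float).ravel()
    if model_field.shape != ref.shape or len(ref) != 3 * len(boundary):
        raise ValueError(
            f"length mismatch: model {model_field.shape}, reference "
            f"{ref.shape}, boundary N={len(boundary)}"
        )
    diff = (model_field - ref).reshape(-1, 3)
    sq = np.sum(diff * diff, axis=-1)
    return sq if squared else np.sqrt(sq)


def fit_field(
    model: MotionModel, field: DisplacementField, k: "int | None" = None
) -> ModelFit:
    """Optimal-weight fit of the model to a field, with residuals.

    ``k=0`` gives the mean-only model; the no-model baseline is a separate
    concept (residual against the zero field) handled by the evaluation
    layer.
    """
    if k is None:
        k = model.n_components
    w = optimal_weights(model, field, k)
    recon = reconstruct(model, w, k)
    res = residuals(recon, field, model.boundary)
    return ModelFit(weights=w, residuals=res, n_components_used=k)


def cumulative_variance(model: "MotionModel | np.ndarray") -> np.ndarray:
    """Cumulative fraction of variance explained per component count;
    the last entry is 1 by construction."""
    eig = model.eigenvalues if isinstance(model, MotionModel) else np.asarray(
        model, dtype=float
    )
    total = eig.sum()
    if total <= 0:
        raise ValueError("cumulative variance undefined: all eigenvalues zero")
    return np.cumsum(eig) / total
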