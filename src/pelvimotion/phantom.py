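"""Synthetic 4D pelvic phantom with known ground-truth motion.

The phantom emulates a short dynamic MR series of the male pelvis: three
ellipsoidal organs (prostate, bladder, rectum) on an anisotropic grid,
deforming slowly and monotonically over ten frames.  The motion
phenomenology mirrors what drives intrafractional pelvic drift:

* the bladder fills, expanding radially a fraction of a millimetre per
  frame;
* the rectum drifts anteriorly with a gently super-linear filling profile;
* the prostate translates rigidly, coupled linearly to bladder and rectal
  filling, plus a small independent relaxation drift.

The deformation is defined *analytically* as a forward displacement
function ``u(p, t)`` (reference coordinates → frame-``t`` coordinates,
millimetres).  Each frame is rendered by inverting this map per voxel with
a fixed-point iteration on the analytic function and evaluating the
analytic reference-frame intensity there, so images, masks and the
ground-truth displacement fields are mutually consistent to well below
voxel size, with no resampling chain.

Axes are ``(x, y, z)`` = (left-right, anterior-posterior with +y
posterior, inferior-superior).  In-plane resolution is finer than
through-plane, as in axial MR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .core import (
    DisplacementField,
    ImageVolume,
    LabelMaskSet,
    jacobian_determinant,
)

__all__ = [
    "Ellipsoid",
    "PhantomConfig",
    "PhantomFrame",
    "PhantomMotionError",
    "generate_series",
]


class PhantomMotionError(ValueError):
    """Raised when configured amplitudes produce a folding (non-invertible)
    ground-truth deformation."""


@dataclass(frozen=True)
class Ellipsoid:
    """Organ geometry: centre and semi-axes in mm."""

    centre_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]

    def radius(self, points: np.ndarray) -> np.ndarray:
        """Normalized ellipsoidal radius (1 on the surface)."""
        rel = (points - np.asarray(self.centre_mm)) / np.asarray(self.semiaxes_mm)
        return np.sqrt(np.sum(rel * rel, axis=-1))


def _default_organs() -> Dict[str, Ellipsoid]:
    # Within a 96 x 96 x 96 mm field of view: bladder superior to the
    # prostate, rectum posterior; masks pairwise disjoint at frame 0.
    return {
        "prostate": Ellipsoid((48.0, 46.0, 38.0), (14.0, 12.0, 11.0)),
        "bladder": Ellipsoid((48.0, 42.0, 66.0), (20.0, 17.0, 14.0)),
        "rectum": Ellipsoid((48.0, 68.0, 44.0), (9.0, 8.0, 26.0)),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic subject.

    Motion amplitudes are per-frame increments in mm; the defaults give a
    total prostate drift of a couple of millimetres over the ten frames,
    with roughly a fifth of the joint boundary moving more than 1 mm by the
    late frames.
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 48)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_frames: int = 10
    organs: Dict[str, Ellipsoid] = field(default_factory=_default_organs)
    # motion amplitudes
    bladder_growth_mm_per_frame: float = 0.13
    rectum_drift_mm_per_frame: float = 0.11
    rectum_direction: Tuple[float, float, float] = (0.0, -1.0, 0.0)
    rectum_filling_power: float = 1.6
    prostate_coupling_bladder: float = 0.35
    prostate_coupling_rectum: float = 0.45
    prostate_direction: Tuple[float, float, float] = (0.0, -0.6, 0.5)
    prostate_relaxation_mm: float = 0.12
    kernel_falloff: float = 0.35  # Gaussian tail width, ellipsoid-radius units
    # appearance
    organ_intensity: Dict[str, float] = field(
        default_factory=lambda: {"prostate": 0.65, "bladder": 0.9, "rectum": 0.12}
    )
    background_intensity: float = 0.35
    edge_width_mm: float = 1.2
    texture_scale: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if min(self.spacing_mm) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        for key in ("bladder", "prostate", "rectum"):
            if key not in self.organs:
                raise ValueError(f"organ geometry missing '{key}'")


@dataclass(frozen=True)
class PhantomFrame:
    """One time frame: image, organ masks and the ground-truth displacement
    field mapping reference-frame coordinates into this frame (mm).

    Frame 0 is the reference; its field is identically zero.  Pulling this
    frame's masks back through ``gt_field`` recovers the frame-0 masks up
    to voxelization.
    """

    image: ImageVolume
    masks: LabelMaskSet
    gt_field: DisplacementField


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


class _Motion:
    """Analytic forward displacement u(p, t) built from per-organ kernels."""

    def __init__(self, cfg: PhantomConfig):
        self.cfg = cfg
        self.rectum_dir = _unit(cfg.rectum_direction)
        self.prostate_dir = _unit(cfg.prostate_direction)

    def _tail(self, rho: np.ndarray) -> np.ndarray:
        """Plateau kernel: 1 inside the organ, Gaussian falloff outside."""
        s = self.cfg.kernel_falloff
        out = np.ones_like(rho)
        outside = rho > 1.0
        out[outside] = np.exp(-(((rho[outside] - 1.0) / s) ** 2))
        return out

    def _radial(self, rho: np.ndarray) -> np.ndarray:
        """Expansion profile: linear ramp inside, Gaussian falloff outside."""
        s = self.cfg.kernel_falloff
        out = np.minimum(rho, 1.0)
        outside = rho > 1.0
        out[outside] = np.exp(-(((rho[outside] - 1.0) / s) ** 2))
        return out

    def amplitudes(self, t: int) -> Tuple[float, float, float]:
        """Bladder, rectum and prostate-relaxation amplitudes at frame t."""
        cfg = self.cfg
        a_bladder = cfg.bladder_growth_mm_per_frame * t
        # super-linear filling, scaled so the per-frame increment averages
        # rectum_drift_mm_per_frame over the series
        tt = t / (cfg.n_frames - 1)
        a_rectum = (
            cfg.rectum_drift_mm_per_frame
            * (cfg.n_frames - 1)
            * tt ** cfg.rectum_filling_power
        )
        a_relax = cfg.prostate_relaxation_mm * np.sqrt(tt)
        return a_bladder, a_rectum, a_relax

    def __call__(self, points: np.ndarray, t: int) -> np.ndarray:
        """Forward displacement in mm at reference coordinates (..., 3)."""
        cfg = self.cfg
        a_bladder, a_rectum, a_relax = self.amplitudes(t)
        u = np.zeros_like(points)

        bladder = cfg.organs["bladder"]
        rel = points - np.asarray(bladder.centre_mm)
        dist = np.linalg.norm(rel, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            radial_dir = np.where(dist > 1e-9, rel / dist, 0.0)
        rho_b = bladder.radius(points)
        u += a_bladder * self._radial(rho_b)[..., None] * radial_dir

        rho_r = cfg.organs["rectum"].radius(points)
        u += a_rectum * self._tail(rho_r)[..., None] * self.rectum_dir

        rho_p = cfg.organs["prostate"].radius(points)
        a_prostate = (
            cfg.prostate_coupling_bladder * a_bladder
            + cfg.prostate_coupling_rectum * a_rectum
            + a_relax
        )
        u += a_prostate * self._tail(rho_p)[..., None] * self.prostate_dir
        return u


class _Appearance:
    """Analytic reference-frame intensity: smooth-edged organs over a soft
    tissue background, plus a low-frequency cosine texture that travels
    with the anatomy."""

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator):
        self.cfg = cfg
        n_waves = 6
        self.wave_dirs = rng.normal(size=(n_waves, 3))
        self.wave_dirs /= np.linalg.norm(self.wave_dirs, axis=1, keepdims=True)
        self.wave_freq = 2 * np.pi / rng.uniform(15.0, 40.0, size=n_waves)
        self.wave_phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        self.wave_amp = cfg.texture_scale * rng.uniform(0.5, 1.0, size=n_waves)
        self.wave_amp /= max(np.sqrt(n_waves / 2.0), 1.0)

    def texture(self, points: np.ndarray) -> np.ndarray:
        out = np.zeros(points.shape[:-1])
        for d, f, ph, a in zip(
            self.wave_dirs, self.wave_freq, self.wave_phase, self.wave_amp
        ):
            out += a * np.cos(f * (points @ d) + ph)
        return out

    def intensity(self, points: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        img = np.full(points.shape[:-1], cfg.background_intensity)
        for name, organ in cfg.organs.items():
            rho = organ.radius(points)
            w_rho = cfg.edge_width_mm / np.exp(
                np.mean(np.log(organ.semiaxes_mm))
            )
            weight = 1.0 / (1.0 + np.exp(-(1.0 - rho) / w_rho))
            img += (cfg.organ_intensity[name] - cfg.background_intensity) * weight
        if cfg.texture_scale > 0:
            img += self.texture(points)
        return img

    def masks(self, points: np.ndarray) -> Dict[str, np.ndarray]:
        return {
            name: organ.radius(points) <= 1.0
            for name, organ in self.cfg.organs.items()
        }


def _grid_points(cfg: PhantomConfig) -> np.ndarray:
    axes = [
        np.arange(n, dtype=float) * s
        for n, s in zip(cfg.grid_shape, cfg.spacing_mm)
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _invert_analytic(
    motion: _Motion, points: np.ndarray, t: int,
    tol_mm: float = 1e-4, max_iter: int = 60,
) -> np.ndarray:
    """Per-point fixed-point solve of q + u(q, t) = p on the analytic
    forward map, so frames can be rendered by pure pull-back."""
    q = points - motion(points, t)
    for _ in range(max_iter):
        q_new = points - motion(q, t)
        step = np.max(np.abs(q_new - q))
        q = q_new
        if step < tol_mm:
            break
    return q


def generate_series(config: PhantomConfig) -> List[PhantomFrame]:
    """Generate the full time series for one synthetic subject.

    Returns ``config.n_frames`` frames.  Deterministic: identical config
    (including seed) gives bit-identical output.  Raises
    :class:`PhantomMotionError` if the configured amplitudes fold the
    ground-truth deformation (non-positive Jacobian) at any frame.
    """
    rng = np.random.default_rng(config.seed)
    motion = _Motion(config)
    appearance = _Appearance(config, rng)
    points = _grid_points(config)

    mask0 = appearance.masks(points)
    names = list(mask0)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = int(np.sum(mask0[a] & mask0[b]))
            if overlap:
                raise ValueError(
                    f"organ masks '{a}' and '{b}' overlap at frame 0 "
                    f"({overlap} voxels); adjust the geometry"
                )

    frames: List[PhantomFrame] = []
    for t in range(config.n_frames):
        if t == 0:
            ref_coords = points
            u = np.zeros_like(points)
        else:
            ref_coords = _invert_analytic(motion, points, t)
            u = motion(points, t)
        gt = DisplacementField(
            u, spacing_mm=config.spacing_mm, origin_mm=(0.0, 0.0, 0.0)
        )
        if t > 0:
            min_jac = float(jacobian_determinant(gt).min())
            if min_jac <= 0:
                raise PhantomMotionError(
                    f"ground-truth deformation folds at frame {t} "
                    f"(min Jacobian determinant {min_jac:.3g}); "
                    "reduce the motion amplitudes"
                )
        voxels = appearance.intensity(ref_coords)
        if config.noise_sd > 0:
            voxels = voxels + rng.normal(0.0, config.noise_sd, voxels.shape)
        image = ImageVolume(
            voxels, spacing_mm=config.spacing_mm, origin_mm=(0.0, 0.0, 0.0)
        )
        masks = LabelMaskSet(
            appearance.masks(ref_coords),
            spacing_mm=config.spacing_mm,
            origin_mm=(0.0, 0.0, 0.0),
        )
        frames.append(PhantomFrame(image=image, masks=masks, gt_field=gt))
    return frames


def vary_subject(base: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Draw a subject-specific variant of a configuration: motion size and
    direction differ between subjects, as they do between real patients."""
    direction = rng.normal(size=3) * np.array([0.3, 1.0, 1.0])
    direction[1] = -abs(direction[1])  # anterior push
    return replace(
        base,
        bladder_growth_mm_per_frame=base.bladder_growth_mm_per_frame
        * rng.uniform(0.6, 1.5),
        rectum_drift_mm_per_frame=base.rectum_drift_mm_per_frame
        * rng.uniform(0.5, 1.5),
        prostate_direction=tuple(float(c) for c in _unit(direction)),
        prostate_coupling_bladder=base.prostate_coupling_bladder
        * rng.uniform(0.7, 1.3),
        prostate_coupling_rectum=base.prostate_coupling_rectum
        * rng.uniform(0.7, 1.3),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
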