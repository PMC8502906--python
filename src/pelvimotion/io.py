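"""NIfTI and manifest I/O.

Scalar volumes and 3-component displacement fields are written as NIfTI
(via nibabel) with a diagonal affine built from the grid spacing and
origin.  A phantom series is laid out as one image, one mask per organ
and one ground-truth vector field per frame, listed in temporal order by
a YAML manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import nibabel as nib
import numpy as np
import yaml

from .core import DisplacementField, ImageVolume, LabelMaskSet
from .phantom import PhantomFrame

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_mask_set",
    "write_series",
    "read_series",
]


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    affine = np.diag(list(spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    return affine


def _grid_of(img: nib.Nifti1Image):
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return spacing, origin


def write_image(image: ImageVolume, path) -> None:
    nib.save(
        nib.Nifti1Image(
            image.voxels.astype(np.float32),
            _affine(image.spacing_mm, image.origin_mm),
        ),
        str(path),
    )


def read_image(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D scalar volume, got {data.shape}")
    spacing, origin = _grid_of(img)
    return ImageVolume(data, spacing_mm=spacing, origin_mm=origin)


def write_field(field: DisplacementField, path) -> None:
    nib.save(
        nib.Nifti1Image(
            field.vectors.astype(np.float32),
            _affine(field.spacing_mm, field.origin_mm),
        ),
        str(path),
    )


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-intent layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a 3-component vector volume, got {data.shape}"
        )
    spacing, origin = _grid_of(img)
    return DisplacementField(data, spacing_mm=spacing, origin_mm=origin)


def _write_mask(mask: np.ndarray, spacing, origin, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing, origin)),
        str(path),
    )


def read_mask_set(paths: dict, strict: bool = True) -> LabelMaskSet:
    """Read named mask files into a set; grids must agree."""
    masks = {}
    spacing = origin = None
    for name, path in paths.items():
        img = nib.load(str(path))
        masks[name] = np.asarray(img.dataobj) > 0.5
        sp, o = _grid_of(img)
        if spacing is None:
            spacing, origin = sp, o
        elif strict and not np.allclose(spacing, sp):
            raise ValueError(f"{path}: spacing {sp} differs from {spacing}")
    return LabelMaskSet(masks, spacing_mm=spacing, origin_mm=origin)


def write_series(frames: List[PhantomFrame], out_dir) -> Path:
    """Write a phantom series frame by frame plus a YAML manifest.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for t, frame in enumerate(frames):
        entry = {"frame": t, "image": f"frame{t:02d}_image.nii.gz"}
        write_image(frame.image, out / entry["image"])
        entry["masks"] = {}
        for name, mask in frame.masks.items():
            fname = f"frame{t:02d}_mask_{name}.nii.gz"
            _write_mask(mask, frame.masks.spacing_mm, frame.masks.origin_mm,
                        out / fname)
            entry["masks"][name] = fname
        entry["gt_field"] = f"frame{t:02d}_gt_field.nii.gz"
        write_field(frame.gt_field, out / entry["gt_field"])
        entries.append(entry)
    manifest = out / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"frames": entries}, fh, default_flow_style=False)
    return manifest


def read_series(manifest_path) -> List[PhantomFrame]:
    """Read a phantom series back from its manifest, in temporal order."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    root = manifest_path.parent
    frames = []
    for entry in sorted(manifest["frames"], key=lambda e: e["frame"]):
        frames.append(
            PhantomFrame(
                image=read_image(root / entry["image"]),
                masks=read_mask_set(
                    {n: root / p for n, p in entry["masks"].items()}
                ),
                gt_field=read_field(root / entry["gt_field"]),
            )
        )
    return frames
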