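"""File-format glue: NIfTI volumes/masks, delimited planar grids,
YAML phantom configs, and CSV result rows."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import Ellipsoid, GroundTruth, PhantomSpec
from .planar import PlanarImage
from .spect import SpectVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_planar",
    "load_planar",
    "load_phantom_config",
    "save_ground_truth",
]


def _affine(voxel_size_mm: float, ndim: int = 3) -> np.ndarray:
    aff = np.eye(4)
    for i in range(min(ndim, 3)):
        aff[i, i] = voxel_size_mm
    return aff


def save_volume(path: str | Path, counts: np.ndarray, voxel_size_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(counts, dtype=np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path: str | Path, mode: str = "AC-SC") -> SpectVolume:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return SpectVolume(counts=np.asarray(img.dataobj, dtype=float),
                       voxel_size_mm=voxel, mode=mode)


def save_mask(path: str | Path, mask: np.ndarray, voxel_size_mm: float) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_planar(path: str | Path, image: PlanarImage) -> None:
    """Write a planar image as 2-D NIfTI (.nii/.nii.gz) or delimited text."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.Nifti1Image(image.counts.astype(np.float32),
                              _affine(image.pixel_size_mm, ndim=2))
        nib.save(img, str(path))
    else:
        np.savetxt(path, image.counts, delimiter="\t")


def load_planar(
    path: str | Path, view: str, window: str, pixel_size_mm: float | None = None
) -> PlanarImage:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        counts = np.asarray(img.dataobj, dtype=float)
        if counts.ndim == 3 and counts.shape[-1] == 1:
            counts = counts[..., 0]
        pixel = float(img.header.get_zooms()[0])
    else:
        counts = np.loadtxt(path, delimiter="\t")
        if pixel_size_mm is None:
            raise ValueError("pixel_size_mm required for text planar images")
        pixel = pixel_size_mm
    return PlanarImage(counts=counts, pixel_size_mm=pixel, view=view, window=window)


_ELLIPSOID_KEYS = ("body", "lung_left", "lung_right", "liver", "tumor")


def load_phantom_config(path: str | Path) -> PhantomSpec:
    """Build a PhantomSpec from a flat YAML mapping.

    Scalar keys mirror the PhantomSpec fields; organ geometry is given as
    ``<organ>_center_mm: [x, y, z]`` plus ``<organ>_semiaxes_mm: [a, b, c]``
    (or ``tumor_radius_mm`` for the spherical tumor).  Unspecified keys keep
    their defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = {}
    for organ in _ELLIPSOID_KEYS:
        center = cfg.pop(f"{organ}_center_mm", None)
        semi = cfg.pop(f"{organ}_semiaxes_mm", None)
        radius = cfg.pop(f"{organ}_radius_mm", None)
        if center is None and semi is None and radius is None:
            continue
        if center is None:
            raise ValueError(f"{organ}: center_mm required with geometry keys")
        if radius is not None:
            semi = [radius] * 3
        if semi is None:
            raise ValueError(f"{organ}: semiaxes_mm or radius_mm required")
        kwargs[organ] = Ellipsoid(tuple(float(v) for v in center),
                                  tuple(float(v) for v in semi))
    if "grid_shape" in cfg:
        cfg["grid_shape"] = tuple(int(v) for v in cfg["grid_shape"])
    kwargs.update(cfg)
    return PhantomSpec(**kwargs)


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    import pandas as pd

    rows = [{"quantity": "true_lsf", "region": "", "value": truth.true_lsf},
            {"quantity": "tlr_true", "region": "", "value": truth.tlr_true}]
    for region, v in truth.activity_fractions.items():
        rows.append({"quantity": "activity_fraction", "region": region, "value": v})
    for region, v in truth.volumes_ml.items():
        rows.append({"quantity": "volume_ml", "region": region, "value": v})
    for region, v in truth.masses_g.items():
        rows.append({"quantity": "mass_g", "region": region, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)
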