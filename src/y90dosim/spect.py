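"""SPECT-side quantification: volume LSF, iso-contour segmentation,
organ count/volume/mass extraction, and shine-through-corrected lung counts.

The SPECT lung shunt fraction is the count ratio LSF = Lc / (Lc + LVc) with
Lc the lung counts and LVc the whole-liver counts (tumor included) under
CT-derived masks.  Tumor and injected-healthy-liver (IHL) compartments are
segmented on the SPECT volume itself with a region-growing iso-contour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import ndimage

from .planar import METHOD_SPECT_ACSC, METHOD_SPECT_NOACSC, ShuntResult, UndefinedLsfError

__all__ = [
    "SpectVolume",
    "RoiSet3D",
    "OrganCounts",
    "DEFAULT_DENSITIES",
    "lsf_spect",
    "segment_isocontour",
    "organ_counts",
    "shine_corrected_lung_counts",
]

SpectMode = Literal["AC-SC", "NoAC-SC", "NoAC-NoSC"]
SPECT_MODES = ("AC-SC", "NoAC-SC", "NoAC-NoSC")

#: Tissue densities in g/mL used for mass-from-volume conversion.
DEFAULT_DENSITIES: Mapping[str, float] = {
    "lung": 0.3,
    "liver": 1.03,
    "tumor": 1.03,
    "ihl": 1.03,
}

_METHOD_BY_MODE = {"AC-SC": METHOD_SPECT_ACSC, "NoAC-SC": METHOD_SPECT_NOACSC}


@dataclass
class SpectVolume:
    """A 3-D count volume tagged with its correction mode."""

    counts: np.ndarray
    voxel_size_mm: float
    mode: SpectMode

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("SPECT volume must be 3-D")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("SPECT volume contains non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("SPECT volume contains negative counts")
        if self.mode not in SPECT_MODES:
            raise ValueError(f"unknown SPECT mode {self.mode!r}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3


@dataclass
class RoiSet3D:
    """Organ masks on the SPECT grid.

    ``tumor_mask`` must lie inside ``liver_mask``; ``ihl_mask`` defaults to
    liver minus tumor (the injected healthy liver is the non-tumor target
    compartment).  ``lung_left_mask`` is optional; when absent, helpers split
    the lungs at the mid-sagittal plane of the lung bounding box.
    """

    lung_mask: np.ndarray
    liver_mask: np.ndarray
    tumor_mask: np.ndarray | None = None
    ihl_mask: np.ndarray | None = None
    lung_left_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        self.liver_mask = np.asarray(self.liver_mask, dtype=bool)
        if self.lung_mask.shape != self.liver_mask.shape:
            raise ValueError("lung and liver masks must share a grid")
        if np.any(self.lung_mask & self.liver_mask):
            raise ValueError("lung and liver masks overlap")
        if self.tumor_mask is not None:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if self.tumor_mask.shape != self.liver_mask.shape:
                raise ValueError("tumor mask grid mismatch")
            if np.any(self.tumor_mask & ~self.liver_mask):
                raise ValueError("tumor mask extends outside the liver")
            if self.ihl_mask is None:
                self.ihl_mask = self.liver_mask & ~self.tumor_mask
        if self.ihl_mask is not None:
            self.ihl_mask = np.asarray(self.ihl_mask, dtype=bool)
            if self.ihl_mask.shape != self.liver_mask.shape:
                raise ValueError("IHL mask grid mismatch")
        if self.lung_left_mask is not None:
            self.lung_left_mask = np.asarray(self.lung_left_mask, dtype=bool)
            if self.lung_left_mask.shape != self.lung_mask.shape:
                raise ValueError("left-lung mask grid mismatch")


@dataclass
class OrganCounts:
    """Counts, volumes (mL) and masses (g) per region."""

    lc: float
    lvc: float
    tumor_counts: float
    ihl_counts: float
    volumes_ml: dict
    masses_g: dict


def lsf_spect(lc: float, lvc: float, mode: SpectMode = "AC-SC") -> ShuntResult:
    """Lung shunt fraction from SPECT lung and liver counts."""
    if lc < 0 or lvc < 0:
        raise ValueError("counts must be non-negative")
    if lc + lvc == 0:
        raise UndefinedLsfError("lung + liver counts are zero")
    method = _METHOD_BY_MODE.get(mode, f"LSFspect({mode})")
    return ShuntResult(lsf=lc / (lc + lvc), method=method, counts={"Lc": lc, "LVc": lvc})


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_isocontour(
    volume: SpectVolume,
    seed_point: tuple[int, int, int],
    threshold_fraction: float = 0.40,
    box: tuple[slice, slice, slice] | None = None,
) -> np.ndarray:
    """Region-growing iso-contour segmentation.

    Thresholds the volume (restricted to ``box``, default the whole grid) at
    ``threshold_fraction`` of the maximum intensity inside the box and
    returns the 26-connected component containing ``seed_point``.
    Deterministic; the result is a boolean mask on the full grid.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    seed = tuple(int(i) for i in seed_point)
    if len(seed) != 3 or any(
        not 0 <= i < s for i, s in zip(seed, volume.counts.shape)
    ):
        raise ValueError(f"seed point {seed} outside the volume")

    region = np.zeros(volume.counts.shape, dtype=bool)
    sl = box if box is not None else tuple(slice(None) for _ in range(3))
    sub = volume.counts[sl]
    threshold = threshold_fraction * float(sub.max())
    above = np.zeros_like(region)
    above[sl] = sub >= threshold
    if not above[seed]:
        raise ValueError(
            f"seed voxel intensity {volume.counts[seed]} below the "
            f"iso-contour threshold {threshold}"
        )
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    region = labels == labels[seed]
    return region


def organ_counts(
    volume: SpectVolume,
    rois: RoiSet3D,
    densities: Mapping[str, float] = DEFAULT_DENSITIES,
) -> OrganCounts:
    """Extract counts, volumes and masses for lung/liver/tumor/IHL."""
    if rois.lung_mask.shape != volume.counts.shape:
        raise ValueError(
            f"ROI grid {rois.lung_mask.shape} does not match volume grid "
            f"{volume.counts.shape}"
        )
    vox_ml = volume.voxel_volume_ml
    masks = {"lung": rois.lung_mask, "liver": rois.liver_mask}
    if rois.tumor_mask is not None:
        masks["tumor"] = rois.tumor_mask
    if rois.ihl_mask is not None:
        masks["ihl"] = rois.ihl_mask
    counts = {k: float(volume.counts[m].sum()) for k, m in masks.items()}
    volumes = {k: float(m.sum()) * vox_ml for k, m in masks.items()}
    masses = {k: volumes[k] * densities[k] for k in masks}
    return OrganCounts(
        lc=counts["lung"],
        lvc=counts["liver"],
        tumor_counts=counts.get("tumor", 0.0),
        ihl_counts=counts.get("ihl", 0.0),
        volumes_ml=volumes,
        masses_g=masses,
    )


def split_left_lung(lung_mask: np.ndarray) -> np.ndarray:
    """Left-lung submask: voxels on the low-x side of the mid-sagittal plane
    of the lung bounding box (x is the left-right axis)."""
    xs = np.where(lung_mask.any(axis=(1, 2)))[0]
    if xs.size == 0:
        raise ValueError("empty lung mask")
    mid = (xs[0] + xs[-1] + 1) / 2.0
    left = np.zeros_like(lung_mask)
    x_idx = np.arange(lung_mask.shape[0])
    left[x_idx < mid, :, :] = True
    return lung_mask & left


def shine_corrected_lung_counts(
    volume: SpectVolume,
    rois: RoiSet3D,
    margin_mm: float = 20.0,
) -> float:
    """Lung counts corrected for liver shine-through.

    The liver mask is expanded by ``margin_mm``; the expansion zone is
    excluded from the left lung, the left-lung count concentration
    (counts/cm^3) is measured on the remainder, and that concentration is
    scaled by the total (unexpanded) lung volume.  This suppresses spill of
    liver counts into the lung base from scatter, resolution, and
    SPECT/CT misregistration.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if rois.lung_mask.shape != volume.counts.shape:
        raise ValueError("ROI grid does not match volume grid")
    left = rois.lung_left_mask
    if left is None:
        left = split_left_lung(rois.lung_mask)
    # Expand the liver by margin_mm via the Euclidean distance to the mask.
    dist = ndimage.distance_transform_edt(
        ~rois.liver_mask, sampling=volume.voxel_size_mm
    )
    dilated_liver = dist <= margin_mm
    clean_left = left & ~dilated_liver
    n_clean = int(clean_left.sum())
    if n_clean == 0:
        raise ValueError(
            "left lung entirely removed by the expanded liver margin; "
            "cannot estimate a clean count concentration"
        )
    vox_ml = volume.voxel_volume_ml
    conc_per_ml = float(volume.counts[clean_left].sum()) / (n_clean * vox_ml)
    total_lung_ml = float(rois.lung_mask.sum()) * vox_ml
    return conc_per_ml * total_lung_ml
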