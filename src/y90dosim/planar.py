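"""Conjugate-view planar quantification of the lung shunt fraction.

Whole-body scintigraphy after intra-arterial :sup:`99m`Tc-MAA yields an
anterior/posterior image pair in the 140 keV photopeak window and one
down-scatter window.  The lung shunt fraction (LSF) is formed from the
geometric means of the lung and liver region-of-interest counts,

    LSF = sqrt(La * Lp) / (sqrt(La * Lp) + sqrt(Lva * Lvp)),

optionally after dual-energy-window (DEW) scatter correction of each ROI
count,

    C_true = C_main - (C_low / W_low) * W_main / 2,

where ``W_main`` and ``W_low`` are the fractional window widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PlanarImage",
    "EnergyWindowPair",
    "RoiSet2D",
    "ShuntResult",
    "UndefinedLsfError",
    "extract_roi_counts",
    "dew_correct",
    "geometric_mean_lsf",
    "lsf_planar",
]

View = Literal["anterior", "posterior"]
Window = Literal["peak", "downscatter"]

#: Method tags used throughout the package for the four LSF estimators.
METHOD_WB_ST = "LSFwb(St)"
METHOD_WB_SC = "LSFwb(SC)"
METHOD_SPECT_ACSC = "LSFspect(AC-SC)"
METHOD_SPECT_NOACSC = "LSFspect(NoAC-SC)"


class UndefinedLsfError(ValueError):
    """All organ counts are zero: the shunt fraction is undefined."""


@dataclass
class PlanarImage:
    """One planar view in one energy window.

    Parameters
    ----------
    counts : 2-D array of non-negative, finite count values.
    pixel_size_mm : isotropic pixel edge length.
    view : ``"anterior"`` or ``"posterior"``.
    window : ``"peak"`` or ``"downscatter"``.
    """

    counts: np.ndarray
    pixel_size_mm: float
    view: View
    window: Window

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("planar image must be 2-D")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("planar image contains non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("planar image contains negative counts")
        if self.view not in ("anterior", "posterior"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.window not in ("peak", "downscatter"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")


@dataclass(frozen=True)
class EnergyWindowPair:
    """Fractional widths of the photopeak and down-scatter windows."""

    w_main: float = 0.15
    w_low: float = 0.15

    def __post_init__(self) -> None:
        for name, w in (("w_main", self.w_main), ("w_low", self.w_low)):
            if not 0 < w < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {w}")


@dataclass
class RoiSet2D:
    """Disjoint lung and liver masks congruent with the planar images."""

    lung_mask: np.ndarray
    liver_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        self.liver_mask = np.asarray(self.liver_mask, dtype=bool)
        if self.lung_mask.shape != self.liver_mask.shape:
            raise ValueError("lung and liver masks must share a grid")
        if np.any(self.lung_mask & self.liver_mask):
            raise ValueError("lung and liver ROIs overlap")


@dataclass
class ShuntResult:
    """A lung shunt fraction together with its provenance.

    ``counts`` holds the organ counts the estimate was formed from:
    ``{"La", "Lp", "Lva", "Lvp"}`` for planar estimates or
    ``{"Lc", "LVc"}`` for SPECT estimates.
    """

    lsf: float
    method: str
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lsf <= 1.0:
            raise ValueError(f"LSF out of range [0, 1]: {self.lsf}")


def extract_roi_counts(image: PlanarImage, rois: RoiSet2D) -> tuple[float, float]:
    """Sum the image counts under the lung and liver masks."""
    if rois.lung_mask.shape != image.counts.shape:
        raise ValueError(
            f"ROI grid {rois.lung_mask.shape} does not match image grid "
            f"{image.counts.shape}"
        )
    lung = float(image.counts[rois.lung_mask].sum())
    liver = float(image.counts[rois.liver_mask].sum())
    return lung, liver


def dew_correct(
    c_main: float, c_low: float, windows: EnergyWindowPair = EnergyWindowPair()
) -> float:
    """Dual-energy-window scatter correction of an ROI count.

    Returns ``c_main - (c_low / w_low) * w_main / 2``, floored at zero:
    counts are physical and Poisson noise can drive the estimate negative.
    With equal window widths the rule reduces to ``c_main - c_low / 2``.
    """
    if c_main < 0 or c_low < 0:
        raise ValueError("counts must be non-negative")
    corrected = c_main - (c_low / windows.w_low) * windows.w_main / 2.0
    return max(corrected, 0.0)


def geometric_mean_lsf(
    la: float, lp: float, lva: float, lvp: float, method: str = METHOD_WB_ST
) -> ShuntResult:
    """Geometric-mean lung shunt fraction from conjugate-view organ counts.

    Parameters are the lung anterior/posterior and liver anterior/posterior
    counts.  The geometric mean sqrt(A*P) suppresses the depth dependence of
    attenuation that either single view would carry.
    """
    counts = {"La": la, "Lp": lp, "Lva": lva, "Lvp": lvp}
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"{name} must be non-negative, got {c}")
    gm_lung = float(np.sqrt(la * lp))
    gm_liver = float(np.sqrt(lva * lvp))
    if gm_lung + gm_liver == 0.0:
        raise UndefinedLsfError(
            "all organ counts are zero; cannot distinguish missing data "
            "from a true zero shunt"
        )
    return ShuntResult(lsf=gm_lung / (gm_lung + gm_liver), method=method, counts=counts)


def lsf_planar(
    anterior_peak: PlanarImage,
    posterior_peak: PlanarImage,
    anterior_low: PlanarImage,
    posterior_low: PlanarImage,
    rois: RoiSet2D,
    windows: EnergyWindowPair = EnergyWindowPair(),
    mode: Literal["standard", "scatter_corrected"] = "standard",
) -> ShuntResult:
    """Planar LSF from the four whole-body images.

    ``standard`` uses the raw photopeak ROI counts; ``scatter_corrected``
    applies the DEW correction to each organ's ROI sum per view first.  The
    correction is applied to ROI sums rather than pixel-wise: the DEW rule is
    linear, so the two orders agree in expectation, and the published rule is
    stated on counts.
    """
    expected = {
        "anterior_peak": ("anterior", "peak"),
        "posterior_peak": ("posterior", "peak"),
        "anterior_low": ("anterior", "downscatter"),
        "posterior_low": ("posterior", "downscatter"),
    }
    images = {
        "anterior_peak": anterior_peak,
        "posterior_peak": posterior_peak,
        "anterior_low": anterior_low,
        "posterior_low": posterior_low,
    }
    for name, (view, window) in expected.items():
        img = images[name]
        if img.view != view or img.window != window:
            raise ValueError(
                f"{name} must be tagged ({view}, {window}), got "
                f"({img.view}, {img.window})"
            )
    if mode not in ("standard", "scatter_corrected"):
        raise ValueError(f"unknown mode {mode!r}")

    la, lva = extract_roi_counts(anterior_peak, rois)
    lp, lvp = extract_roi_counts(posterior_peak, rois)
    if mode == "scatter_corrected":
        la_low, lva_low = extract_roi_counts(anterior_low, rois)
        lp_low, lvp_low = extract_roi_counts(posterior_low, rois)
        la = dew_correct(la, la_low, windows)
        lp = dew_correct(lp, lp_low, windows)
        lva = dew_correct(lva, lva_low, windows)
        lvp = dew_correct(lvp, lvp_low, windows)
        method = METHOD_WB_SC
    else:
        method = METHOD_WB_ST
    return geometric_mean_lsf(la, lp, lva, lvp, method=method)
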