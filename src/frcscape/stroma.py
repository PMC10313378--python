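"""Pixel-level stromal compartment mapping.

Pixels are classified by a two-marker decision rule on podoplanin (PDPN)
and CD31: PDPN+CD31- -> FRC, PDPN+CD31+ -> LEC (lymphatic endothelium),
PDPN-CD31+ -> BEC (blood endothelium), otherwise background.  Thresholds
default to per-channel Otsu after light Gaussian smoothing
(sigma 0.7 px, roughly a 1 px FWHM window); fixed
thresholds can be supplied instead.  Pixels exactly at a threshold count
as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, ParameterError
from .io import MultiplexImage

STROMA_CLASS_NAMES = {0: "none", 1: "FRC", 2: "LEC", 3: "BEC"}
NONE, FRC, LEC, BEC = 0, 1, 2, 3


@dataclass
class StromaMap:
    """Per-pixel stromal class raster with the thresholds that produced it."""

    class_raster: np.ndarray  # uint8, codes above
    thresholds_used: dict[str, float]
    pixel_size_um: float

    def mask(self, klass: int) -> np.ndarray:
        return self.class_raster == klass

    @property
    def frc_mask(self) -> np.ndarray:
        return self.mask(FRC)


def classify_stroma_pixels(
    image: MultiplexImage,
    method: str = "otsu",
    fixed_thresholds: dict[str, float] | None = None,
    smoothing_sigma_px: float = 0.7,
) -> StromaMap:
    """Classify every pixel into {FRC, LEC, BEC, none}.

    The channels used are only those named in the panel, so the result is
    invariant to channel order.
    """
    if method not in ("otsu", "fixed"):
        raise ParameterError(f"unknown thresholding method {method!r}")
    pdpn = image.channel("PDPN").astype(float)
    cd31 = image.channel("CD31").astype(float)
    if smoothing_sigma_px > 0:
        pdpn = ndimage.gaussian_filter(pdpn, smoothing_sigma_px)
        cd31 = ndimage.gaussian_filter(cd31, smoothing_sigma_px)

    thresholds: dict[str, float] = {}
    for name, chan in (("PDPN", pdpn), ("CD31", cd31)):
        if method == "fixed":
            if not fixed_thresholds or name not in fixed_thresholds:
                raise ParameterError(f"fixed threshold for {name} not provided")
            thresholds[name] = float(fixed_thresholds[name])
        else:
            thresholds[name] = (
                float(threshold_otsu(chan)) if np.ptp(chan) > 0 else float(np.inf)
            )

    pdpn_pos = pdpn >= thresholds["PDPN"]
    cd31_pos = cd31 >= thresholds["CD31"]
    raster = np.zeros(pdpn.shape, dtype=np.uint8)
    raster[pdpn_pos & ~cd31_pos] = FRC
    raster[pdpn_pos & cd31_pos] = LEC
    raster[~pdpn_pos & cd31_pos] = BEC
    return StromaMap(raster, thresholds, image.panel.pixel_size_um)


def area_occupied(
    stroma: StromaMap,
    denominator: str = "field",
    tissue_mask: np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """Fraction (and mm^2) of each stromal class over field or tissue mask."""
    if denominator == "field":
        denom_mask = np.ones(stroma.class_raster.shape, dtype=bool)
    elif denominator == "tissue_mask":
        if tissue_mask is None or not tissue_mask.any():
            raise DegenerateInputError("tissue mask is empty")
        denom_mask = tissue_mask.astype(bool)
    else:
        raise ParameterError(f"unknown denominator {denominator!r}")
    denom = int(denom_mask.sum())
    px_mm2 = (stroma.pixel_size_um / 1000.0) ** 2
    out = {}
    for code, name in STROMA_CLASS_NAMES.items():
        n = int(((stroma.class_raster == code) & denom_mask).sum())
        out[name] = {"fraction": n / denom, "area_mm2": n * px_mm2}
    return out


def _frc_values(image: MultiplexImage, stroma: StromaMap, marker: str) -> np.ndarray:
    mask = stroma.frc_mask
    if not mask.any():
        raise DegenerateInputError("stroma map contains no FRC pixels")
    return image.channel(marker)[mask]


def frc_marker_intensity(
    image: MultiplexImage, stroma: StromaMap, marker: str
) -> dict[str, float]:
    """Mean and median intensity of a marker over FRC-class pixels."""
    vals = _frc_values(image, stroma, marker)
    return {"mean": float(vals.mean()), "median": float(np.median(vals)), "n_pixels": int(vals.size)}


def frc_positive_fraction(
    image: MultiplexImage,
    stroma: StromaMap,
    marker: str,
    positivity_threshold: float,
) -> dict[str, float]:
    """Fraction of FRC pixels with marker >= threshold (e.g. FAP+ FRCs)."""
    vals = _frc_values(image, stroma, marker)
    return {
        "fraction": float((vals >= positivity_threshold).mean()),
        "threshold": float(positivity_threshold),
        "n_pixels": int(vals.size),
    }


def frc_positive_fraction_objects(
    image: MultiplexImage,
    stroma: StromaMap,
    marker: str,
    positivity_threshold: float,
    min_area_px: int = 9,
) -> dict[str, float]:
    """Object-level variant: fraction of connected FRC components whose
    mean marker intensity reaches the threshold.  Not the default readout
    (the pixel-level fraction is), but useful when positivity is expected
    to segregate by fiber rather than by pixel."""
    from skimage.measure import label as cc_label, regionprops

    mask = stroma.frc_mask
    if not mask.any():
        raise DegenerateInputError("stroma map contains no FRC pixels")
    labels = cc_label(mask, connectivity=2)
    chan = image.channel(marker)
    means = [
        float(chan[labels == p.label].mean())
        for p in regionprops(labels)
        if p.area >= min_area_px
    ]
    if not means:
        raise DegenerateInputError("no FRC components above the size floor")
    means = np.asarray(means)
    return {
        "fraction": float((means >= positivity_threshold).mean()),
        "threshold": float(positivity_threshold),
        "n_objects": int(means.size),
    }
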