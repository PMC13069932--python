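"""Brightfield IHC field quantification.

Replicates an ImageJ-style workflow on 8-bit grayscale field images
(0 = black = most intense stain, 255 = white = unstained background):
a gray-level threshold at the midpoint of the minimum and maximum pixel
values selects the stained area, from which two measurements are taken —
the mean intensity of the stained pixels and the percent of the field
area stained. Per-slide values are unweighted means over the (typically
three) fields captured for that slide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Reference white level of 8-bit brightfield images.
WHITE_REF = 255.0

# Rec. 601 luminance weights used to collapse RGB input to intensity.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateImageError(ValueError):
    """Raised when an image or ROI cannot be quantified at all."""


@dataclass(frozen=True)
class FieldQuant:
    """Measurements for a single microscope field.

    ``mean_intensity`` is NaN when no pixel falls below the threshold
    (an unstained field); ``pct_area`` is in percent units (0-100).
    """

    field_id: str
    threshold: float
    mean_intensity: float
    pct_area: float
    n_stained: int
    n_total: int


@dataclass(frozen=True)
class SlideQuant:
    """Unweighted per-slide aggregate of field measurements."""

    slide_id: str
    fields: tuple[FieldQuant, ...]
    agg_mean_intensity: float
    agg_pct_area: float

    @property
    def quantifiable(self) -> bool:
        return not np.isnan(self.agg_mean_intensity)


def as_gray(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to a 2-D float grid of gray values in [0, 255].

    RGB(A) input is collapsed by Rec. 601 luminance weighting; 16-bit
    input is rescaled to the 8-bit range with a warning.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image array, got shape {arr.shape}")
    arr = arr.astype(float)
    if arr.size == 0:
        raise DegenerateImageError("empty image")
    if arr.max() > 255.0:
        warnings.warn("16-bit image rescaled to 8-bit range", stacklevel=2)
        arr = arr * (255.0 / 65535.0)
    if arr.min() < 0.0:
        raise ValueError("negative pixel values are not valid gray levels")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG/TIFF field image as a gray-value grid."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    return as_gray(arr)


def compute_threshold(image: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """Midpoint threshold: (min + max) / 2 over the analysis region.

    A constant region is degenerate — the threshold equals the constant
    and strict-inequality segmentation yields an empty mask; this is
    logged rather than raised so unstained fields flow through as
    zero-area measurements.
    """
    gray = as_gray(image)
    pixels = _select(gray, roi)
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo == hi:
        logger.warning("constant image region (gray=%g): threshold degenerate", lo)
    return (lo + hi) / 2.0


def segment_stain(image: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean stain mask: true exactly where pixel < threshold.

    Ties at the threshold count as unstained (conservative toward less
    staining).
    """
    if not 0.0 <= threshold <= 255.0:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    return as_gray(image) < threshold


def quantify_field(
    image: np.ndarray,
    roi: Optional[np.ndarray] = None,
    field_id: str = "field",
) -> FieldQuant:
    """Threshold, segment and measure one field.

    Returns the threshold used, the mean gray value of stained pixels
    (NaN if none), and the stained percentage of the analysis region.
    """
    gray = as_gray(image)
    threshold = compute_threshold(gray, roi)
    mask = gray < threshold
    if roi is not None:
        roi = _check_roi(gray, roi)
        mask &= roi
        n_total = int(roi.sum())
    else:
        n_total = gray.size
    n_stained = int(mask.sum())
    pct_area = 100.0 * n_stained / n_total
    mean_intensity = float(gray[mask].mean()) if n_stained else float("nan")
    logger.info(
        "%s: threshold=%.3f pct_area=%.3f mean_intensity=%.3f",
        field_id, threshold, pct_area, mean_intensity,
    )
    return FieldQuant(
        field_id=field_id,
        threshold=threshold,
        mean_intensity=mean_intensity,
        pct_area=pct_area,
        n_stained=n_stained,
        n_total=n_total,
    )


def aggregate_slide(fields: Sequence[FieldQuant], slide_id: str = "slide") -> SlideQuant:
    """Unweighted mean of per-field intensity and area.

    Intensity averages only over fields with a non-empty stain mask; if
    every field is empty the slide is unquantifiable (NaN intensity).
    """
    if not fields:
        raise ValueError("aggregate_slide requires at least one field")
    areas = [f.pct_area for f in fields]
    intensities = [f.mean_intensity for f in fields if f.n_stained > 0]
    if intensities:
        agg_int = float(np.mean(intensities))
    else:
        logger.warning("%s: all fields empty-mask; slide unquantifiable", slide_id)
        agg_int = float("nan")
    return SlideQuant(
        slide_id=slide_id,
        fields=tuple(fields),
        agg_mean_intensity=agg_int,
        agg_pct_area=float(np.mean(areas)),
    )


def _check_roi(gray: np.ndarray, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi).astype(bool)
    if roi.shape != gray.shape:
        raise ValueError(f"ROI shape {roi.shape} != image shape {gray.shape}")
    if not roi.any():
        raise DegenerateImageError("empty ROI")
    return roi


def _select(gray: np.ndarray, roi: Optional[np.ndarray]) -> np.ndarray:
    if roi is None:
        return gray.ravel()
    return gray[_check_roi(gray, roi)]
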