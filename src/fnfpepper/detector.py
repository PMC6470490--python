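"""Color-blob fruit detector.

Deliberately naive threshold-based detection of yellow sweet peppers: pixels
are kept when their hue and saturation fall inside fixed bands (defaults:
hue 20-50 deg, saturation 90-255 on the 8-bit scale), the resulting mask is
cleaned morphologically, connected components are extracted, components
smaller than a resolution-scaled minimum area (default 400 px at 320x240)
are dropped, and each surviving blob is reported with its tight bounding
window.  On FNF composites, where ambient light has been cancelled, these
fixed color bands are stable across illumination conditions.

A lightweight calibration routine recovers the threshold bands from as few
as one to three labeled images, mirroring the quick re-calibration a field
system needs when moving to a new greenhouse or cultivar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing as _closing
from skimage.morphology import opening as _opening

from .imaging import HSVImage, RGBImage, rgb_to_hsv

__all__ = [
    "DetectorParams",
    "Detection",
    "threshold_mask",
    "clean_mask",
    "extract_blobs",
    "filter_blobs",
    "detect",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable parameters of the color-blob detector.

    hue_min, hue_max
        Inclusive hue band in degrees (yellow peppers: 20-50).
    sat_min, sat_max
        Inclusive saturation band on [0, 255] (default 90-255); the value
        channel is left unconstrained.
    min_area_ref, ref_width, ref_height
        Minimum blob area in pixels at the reference resolution; the
        effective minimum scales linearly with the pixel count of the image
        being processed.
    morph_open_size
        Side of the square structuring element for the despeckling opening
        that precedes closing (0 or 1 disables it).  Without it, sensor
        noise in dark regions yields sparse in-band pixels that closing
        would otherwise weld into fruit-sized false blobs.
    morph_close_size
        Side of the square structuring element used for morphological
        closing (0 or 1 disables closing).
    connectivity
        4- or 8-connectivity for component extraction.
    """

    hue_min: float = 20.0
    hue_max: float = 50.0
    sat_min: float = 90.0
    sat_max: float = 255.0
    min_area_ref: int = 400
    ref_width: int = 320
    ref_height: int = 240
    morph_open_size: int = 3
    morph_close_size: int = 5
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.hue_min < self.hue_max:
            raise ValueError("hue_min must be < hue_max")
        if not self.sat_min <= self.sat_max:
            raise ValueError("sat_min must be <= sat_max")
        if self.min_area_ref < 1:
            raise ValueError("min_area_ref must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def min_area_at(self, width: int, height: int) -> float:
        """Minimum blob area scaled to a ``width x height`` image."""
        return self.min_area_ref * (width * height) / (self.ref_width * self.ref_height)


@dataclass(frozen=True)
class Detection:
    """One segmented blob: full-frame boolean mask, pixel area, tight bbox.

    ``bbox`` is ``(x0, y0, x1, y1)`` in 0-based half-open pixel coordinates.
    """

    blob_mask: np.ndarray
    area: int
    bbox: tuple[int, int, int, int]


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1


def threshold_mask(hsv: HSVImage, params: DetectorParams) -> np.ndarray:
    """Boolean mask of pixels inside the hue and saturation bands (inclusive)."""
    return (
        (hsv.hue >= params.hue_min)
        & (hsv.hue <= params.hue_max)
        & (hsv.saturation >= params.sat_min)
        & (hsv.saturation <= params.sat_max)
    )


def clean_mask(mask: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Morphological cleanup: opening, closing, then hole filling.

    The opening removes isolated noise pixels; closing bridges small gaps
    (it is what merges touching fruit into one blob — the cluster behavior
    the evaluation handles explicitly); hole filling removes specular
    dropouts inside fruit.
    """
    out = np.asarray(mask, dtype=bool)
    k_open = params.morph_open_size
    if k_open >= 2:
        out = _opening(out, np.ones((k_open, k_open), dtype=bool))
    k = params.morph_close_size
    if k >= 2:
        out = _closing(out, np.ones((k, k), dtype=bool))
    return ndi.binary_fill_holes(out)


def _label_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    return ndi.generate_binary_structure(2, 1)


def extract_blobs(mask: np.ndarray, params: DetectorParams) -> list[Detection]:
    """Connected components of a mask, in raster-scan order of first pixel."""
    labeled, n = ndi.label(np.asarray(mask, dtype=bool), structure=_label_structure(params.connectivity))
    blobs: list[Detection] = []
    for lab in range(1, n + 1):
        blob = labeled == lab
        blobs.append(Detection(blob_mask=blob, area=int(blob.sum()), bbox=_bbox_of(blob)))
    return blobs


def filter_blobs(
    blobs: Sequence[Detection],
    image_width: int,
    image_height: int,
    params: DetectorParams,
) -> list[Detection]:
    """Drop blobs below the resolution-scaled minimum area; order preserved."""
    min_area = params.min_area_at(image_width, image_height)
    return [b for b in blobs if b.area >= min_area]


def detect(img: RGBImage, params: DetectorParams | None = None) -> list[Detection]:
    """Run the full detector pipeline on one RGB image.

    RGB -> HSV -> hue/saturation threshold -> morphological cleanup ->
    connected components -> minimum-size filter.  Deterministic for fixed
    input and parameters.
    """
    params = params or DetectorParams()
    mask = clean_mask(threshold_mask(rgb_to_hsv(img), params), params)
    return filter_blobs(extract_blobs(mask, params), img.width, img.height, params)


def calibrate_thresholds(
    images: Sequence[RGBImage],
    fruit_masks: Sequence[np.ndarray],
    base: DetectorParams | None = None,
) -> DetectorParams:
    """Recover hue/saturation bands from a handful of labeled images.

    Replaces an interactive thresholding session with a percentile rule over
    the fruit-labeled pixels of at most a few images: the hue band is the
    1st-99th percentile widened outward to whole degrees (strictly, so a
    degenerate single-hue sample still yields a usable band), sat_min is the
    1st percentile of saturation, and sat_max stays at 255.
    """
    if len(images) != len(fruit_masks):
        raise ValueError("images and fruit_masks must have equal length")
    if not images:
        raise ValueError("at least one image is required")
    hues: list[np.ndarray] = []
    sats: list[np.ndarray] = []
    for img, mask in zip(images, fruit_masks):
        m = np.asarray(mask, dtype=bool)
        if m.shape != img.shape:
            raise ValueError("fruit mask dimensions must match the image")
        if m.any():
            hsv = rgb_to_hsv(img)
            hues.append(hsv.hue[m])
            sats.append(hsv.saturation[m])
    if not hues:
        raise ValueError("no fruit pixels labeled in any image")
    hue = np.concatenate(hues)
    sat = np.concatenate(sats)

    def _widen_down(x: float) -> float:
        f = np.floor(x)
        return float(f - 1.0) if f == x else float(f)

    def _widen_up(x: float) -> float:
        c = np.ceil(x)
        return float(c + 1.0) if c == x else float(c)

    hue_min = max(0.0, _widen_down(float(np.percentile(hue, 1))))
    hue_max = min(359.0, _widen_up(float(np.percentile(hue, 99))))
    sat_min = max(0.0, float(np.floor(np.percentile(sat, 1))))
    base = base or DetectorParams()
    return replace(base, hue_min=hue_min, hue_max=hue_max, sat_min=sat_min, sat_max=255.0)
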