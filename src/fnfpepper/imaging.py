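"""Image containers, colorspace conversion and flash/no-flash (FNF) compositing.

The FNF acquisition protocol takes two frames of the same scene in quick
succession, one under a strong artificial light ("flash") and one under
ambient light only ("no-flash").  Subtracting the no-flash frame from the
flash frame leaves the scene as if lit by the artificial source alone,
which removes most of the ambient-illumination variability (sun direction,
shadows, colored skylight) that breaks color-based fruit detection.

This module provides:

* :class:`RGBImage` / :class:`HSVImage` — thin validated wrappers around
  ``numpy`` rasters with explicit channel semantics and value ranges;
* flash/no-flash pair identification in a raw frame stream, which is needed
  because real acquisition rigs drop frames and run at variable frame-rate;
* the saturation-aware subtraction that produces the FNF composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "RGBImage",
    "HSVImage",
    "FNFParams",
    "FNFPair",
    "mean_brightness",
    "classify_pair",
    "scan_stream",
    "compose_images",
    "compose_fnf",
    "rgb_to_hsv",
    "hsv_to_rgb",
]


# ---------------------------------------------------------------------------
# Image containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB raster.

    ``pixels`` is an ``(H, W, 3)`` array of integer intensities in
    ``[0, 255]``.  Any integer dtype is accepted and stored as ``uint8``.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixel intensities must be integers, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel hue/saturation/value rasters.

    Hue is in degrees in ``[0, 360)``; saturation and value are on the 8-bit
    scale ``[0, 255]`` (stored as floats so quantisation is explicit at the
    boundaries, not inside the pipeline).  A pixel with zero saturation has
    hue 0 by convention.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.hue, dtype=float)
        s = np.asarray(self.saturation, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if not (h.shape == s.shape == v.shape) or h.ndim != 2:
            raise ValueError("hue, saturation and value must be equal-shape 2-D arrays")
        if h.min() < 0 or h.max() >= 360:
            raise ValueError("hue must lie in [0, 360)")
        for name, ch in (("saturation", s), ("value", v)):
            if ch.min() < 0 or ch.max() > 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        object.__setattr__(self, "hue", h)
        object.__setattr__(self, "saturation", s)
        object.__setattr__(self, "value", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FNFParams:
    """Parameters of FNF pair identification and compositing.

    brightness_delta_threshold
        Minimum difference in mean frame brightness (intensity units on
        [0, 255]) for two consecutive frames to count as a flash/no-flash
        pair.  The field-calibrated value of the original system was never
        published; the default of 10 is far above the brightness jitter of
        consecutive ambient frames yet far below the gain a near-range flash
        produces.
    saturation_level
        Channel value at or above which a flash pixel channel counts as
        sensor-saturated (overexposed).  Saturated pixels are excluded from
        the subtraction because their recorded value no longer reflects the
        incident light.
    """

    brightness_delta_threshold: float = 10.0
    saturation_level: int = 255

    def __post_init__(self) -> None:
        if not self.brightness_delta_threshold > 0:
            raise ValueError("brightness_delta_threshold must be > 0")
        if not 0 < self.saturation_level <= 255:
            raise ValueError("saturation_level must lie in (0, 255]")


# ---------------------------------------------------------------------------
# Pair identification
# ---------------------------------------------------------------------------

def mean_brightness(img: RGBImage) -> float:
    """Arithmetic mean intensity over all pixels and all three channels."""
    return float(np.mean(img.pixels, dtype=np.float64))


def classify_pair(
    a: RGBImage, b: RGBImage, params: FNFParams | None = None
) -> Optional[tuple[RGBImage, RGBImage]]:
    """Decide whether two frames form a flash/no-flash pair.

    Returns ``(flash, noflash)`` — the brighter frame is the flash frame —
    when the mean-brightness difference strictly exceeds
    ``params.brightness_delta_threshold``, else ``None``.  The decision is
    symmetric in the argument order.
    """
    params = params or FNFParams()
    if a.shape != b.shape:
        raise ValueError(f"frame dimensions differ: {a.shape} vs {b.shape}")
    delta = mean_brightness(a) - mean_brightness(b)
    if abs(delta) <= params.brightness_delta_threshold:
        return None
    return (a, b) if delta > 0 else (b, a)


@dataclass
class FNFPair:
    """A validated (flash, no-flash) frame pair.

    ``frame_indices`` records the positions of the two frames in the source
    stream (flash index first).  The composite is computed lazily.
    """

    flash: RGBImage
    noflash: RGBImage
    frame_indices: tuple[int, int] = (0, 1)
    params: FNFParams = field(default_factory=FNFParams)
    _composite: Optional[RGBImage] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.flash.shape != self.noflash.shape:
            raise ValueError("flash and noflash frames must have identical dimensions")
        delta = mean_brightness(self.flash) - mean_brightness(self.noflash)
        if delta <= self.params.brightness_delta_threshold:
            raise ValueError(
                f"not a valid FNF pair: flash-minus-noflash mean brightness "
                f"{delta:.2f} does not exceed threshold "
                f"{self.params.brightness_delta_threshold}"
            )

    @property
    def composite(self) -> RGBImage:
        if self._composite is None:
            self._composite = compose_images(self.flash, self.noflash, self.params)
        return self._composite


def scan_stream(
    frames: Sequence[RGBImage], params: FNFParams | None = None
) -> list[FNFPair]:
    """Identify flash/no-flash pairs in an ordered frame stream.

    The acquisition rig alternates the artificial light between frames, but
    dropped frames and variable frame-rate break the strict alternation, so
    the stream is scanned: a pair is emitted whenever a frame is followed by
    a frame darker by more than the brightness threshold (the light fires,
    then the ambient-only follow-up arrives).  On a hit the scan advances
    past both frames; frames belonging to no valid pair are skipped.  The
    returned pairs are non-overlapping and in stream order.
    """
    params = params or FNFParams()
    pairs: list[FNFPair] = []
    i = 0
    while i + 1 < len(frames):
        assignment = classify_pair(frames[i], frames[i + 1], params)
        if assignment is not None and assignment[0] is frames[i]:
            pairs.append(
                FNFPair(
                    flash=frames[i],
                    noflash=frames[i + 1],
                    frame_indices=(i, i + 1),
                    params=params,
                )
            )
            i += 2
        else:
            i += 1
    return pairs


# ---------------------------------------------------------------------------
# Compositing
# ---------------------------------------------------------------------------

def compose_images(
    flash: RGBImage, noflash: RGBImage, params: FNFParams | None = None
) -> RGBImage:
    """Saturation-aware FNF subtraction.

    Per pixel: if any flash channel is at or above ``saturation_level`` the
    pixel is excluded from the subtraction and the flash value passes
    through unchanged (an overexposed channel has lost the incident-light
    information, so subtracting ambient from it would create color
    artifacts).  Otherwise the composite is ``flash - noflash`` per channel
    with negative results corrected to 0.
    """
    params = params or FNFParams()
    if flash.shape != noflash.shape:
        raise ValueError("flash and noflash dimensions differ")
    f = flash.pixels.astype(np.int16)
    n = noflash.pixels.astype(np.int16)
    out = np.maximum(f - n, 0)
    saturated = (flash.pixels >= params.saturation_level).any(axis=2)
    out[saturated] = f[saturated]
    return RGBImage(out.astype(np.uint8))


def compose_fnf(pair: FNFPair, params: FNFParams | None = None) -> RGBImage:
    """FNF composite of a validated pair (see :func:`compose_images`)."""
    return compose_images(pair.flash, pair.noflash, params or pair.params)


# ---------------------------------------------------------------------------
# Colorspace
# ---------------------------------------------------------------------------

def rgb_to_hsv(img: RGBImage) -> HSVImage:
    """Standard RGB -> HSV conversion.

    Hue is returned in degrees ``[0, 360)``; saturation and value are
    rescaled to ``[0, 255]`` to match the 8-bit notation the detector
    thresholds are stated in.
    """
    hsv = _skcolor.rgb2hsv(img.pixels.astype(np.float64) / 255.0)
    hue = hsv[..., 0] * 360.0
    hue[hue >= 360.0] = 0.0
    return HSVImage(hue=hue, saturation=hsv[..., 1] * 255.0, value=hsv[..., 2] * 255.0)


def hsv_to_rgb(hsv: HSVImage) -> RGBImage:
    """Inverse conversion; rounds to the nearest 8-bit intensity."""
    stacked = np.stack(
        [hsv.hue / 360.0, hsv.saturation / 255.0, hsv.value / 255.0], axis=-1
    )
    rgb = _skcolor.hsv2rgb(stacked) * 255.0
    return RGBImage(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
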