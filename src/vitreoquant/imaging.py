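"""Photograph preprocessing: green channel, background subtraction, min–max
normalization to the 8-bit range.

The analysis channel is the green channel of the RGB photograph.  A
fluorescence-free (GFP-negative) region supplies the background estimate,
which is subtracted before the image is linearly rescaled so that its
minimum maps to 0 and its maximum to 255.  Rounding is half-away-from-zero,
stated explicitly because half-cases shift segmentation masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon2mask

from .render import ImageMetadata, RawEyeImage

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundRegion",
    "NormalizedImage",
    "Annotation",
    "read_image",
    "write_normalized",
    "extract_green_channel",
    "subtract_background",
    "normalize",
    "load_annotation",
]


@dataclass
class BackgroundRegion:
    """Boolean mask over the image marking a fluorescence-free area."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("background mask must be boolean")
        if int(self.mask.sum()) < 25:
            raise ValueError("background region must contain at least 25 pixels")

    @classmethod
    def from_rect(cls, shape: tuple[int, int], x0: int, y0: int, width: int, height: int) -> "BackgroundRegion":
        mask = np.zeros(shape, dtype=bool)
        mask[y0 : y0 + height, x0 : x0 + width] = True
        return cls(mask)

    @classmethod
    def from_polygon(cls, shape: tuple[int, int], polygon_xy: np.ndarray) -> "BackgroundRegion":
        rc = np.asarray(polygon_xy, dtype=float)[:, ::-1]  # (x, y) -> (row, col)
        return cls(polygon2mask(shape, rc))


@dataclass
class NormalizedImage:
    """Single-channel 8-bit image after background subtraction and rescaling."""

    pixels: np.ndarray  # (H, W) uint8
    source: str = ""
    background_estimate: float = 0.0


@dataclass
class Annotation:
    """Manual annotations for one photograph (image coordinates: origin at the
    top-left pixel center, x rightward, y downward, 0-based)."""

    boundary_xy: np.ndarray  # (N, 2) polygon vertices, pixel units
    background: Optional[BackgroundRegion] = None
    seed_point_xy: Optional[tuple[float, float]] = None
    nasal_side: str = "left"
    diameter_nt_mm: Optional[float] = None
    diameter_is_mm: Optional[float] = None
    pixel_scale: Optional[float] = None


def read_image(path: Union[str, Path], pixel_scale: float, metadata: Optional[ImageMetadata] = None) -> RawEyeImage:
    """Read an 8-bit RGB PNG/TIFF photograph.

    16-bit inputs are linearly rescaled to 8-bit with a logged warning.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        logger.warning("16-bit image %s rescaled to 8-bit", path)
        arr = (arr.astype(np.float64) / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")
    return RawEyeImage(pixels=arr, pixel_scale=pixel_scale, metadata=metadata or ImageMetadata())


def write_normalized(image: NormalizedImage, path: Union[str, Path]) -> None:
    """Write a normalized image as single-channel 8-bit PNG."""
    iio.imwrite(path, image.pixels)


def extract_green_channel(image: RawEyeImage) -> np.ndarray:
    """Return the green channel (the fluorescein analysis channel)."""
    return image.pixels[:, :, 1].copy()


def subtract_background(
    channel: np.ndarray,
    region: BackgroundRegion,
    statistic: str = "mean",
) -> tuple[np.ndarray, float]:
    """Subtract the background level measured in a fluorescence-free region.

    Returns the real-valued, floor-clamped channel and the background
    estimate (mean by default, median via ``statistic="median"``).
    Quantization is deferred to :func:`normalize`.
    """
    if region.mask.shape != channel.shape:
        raise ValueError("background mask shape differs from the channel shape")
    values = channel[region.mask].astype(np.float64)
    if values.size == 0:
        raise ValueError("background region is empty")
    if statistic == "mean":
        estimate = float(values.mean())
    elif statistic == "median":
        estimate = float(np.median(values))
    else:
        raise ValueError(f"unknown background statistic {statistic!r}")
    out = np.maximum(channel.astype(np.float64) - estimate, 0.0)
    return out, estimate


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # values are non-negative here, so half-away-from-zero == floor(x + 0.5)
    return np.floor(x + 0.5)


def normalize(
    channel: np.ndarray,
    source: str = "",
    background_estimate: float = 0.0,
    interior_mask: Optional[np.ndarray] = None,
) -> NormalizedImage:
    """Linearly rescale so the channel minimum maps to 0 and maximum to 255.

    A constant channel maps to all zeros (no signal).  With
    ``interior_mask`` given, the min/max are computed over that mask only
    (e.g. the eye interior) while the mapping is applied to the whole image,
    clipped to [0, 255].
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty image")
    ref = arr[interior_mask] if interior_mask is not None else arr
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        pixels = np.zeros(arr.shape, dtype=np.uint8)
    else:
        scaled = (arr - lo) * (255.0 / (hi - lo))
        pixels = np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)
    return NormalizedImage(pixels=pixels, source=source, background_estimate=background_estimate)


def load_annotation(path: Union[str, Path], image_shape: tuple[int, int]) -> Annotation:
    """Load a JSON annotation file.

    Expected keys: ``boundary`` (list of [x, y] vertices, required),
    ``background`` (polygon or ``{"rect": [x, y, w, h]}``), ``seed_point``,
    ``nasal_side``, ``diameter_nt_mm``, ``diameter_is_mm``,
    ``pixel_scale_mm``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if "boundary" not in data:
        raise ValueError(f"annotation {path} lacks a 'boundary' polygon")
    boundary = np.asarray(data["boundary"], dtype=float)
    background = None
    bg = data.get("background")
    if bg is not None:
        if isinstance(bg, dict) and "rect" in bg:
            x0, y0, w, h = bg["rect"]
            background = BackgroundRegion.from_rect(image_shape, x0, y0, w, h)
        else:
            background = BackgroundRegion.from_polygon(image_shape, np.asarray(bg, dtype=float))
    seed = data.get("seed_point")
    return Annotation(
        boundary_xy=boundary,
        background=background,
        seed_point_xy=tuple(seed) if seed is not None else None,
        nasal_side=data.get("nasal_side", "left"),
        diameter_nt_mm=data.get("diameter_nt_mm"),
        diameter_is_mm=data.get("diameter_is_mm"),
        pixel_scale=data.get("pixel_scale_mm"),
    )
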