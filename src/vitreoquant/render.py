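"""Forward camera model: concentration field -> noisy RGB fluorescence photo.

The fluorescein signal lands in the green channel: ``green = clip(background
+ gain * C + vignette + noise, 0, 255)``.  Red and blue carry only half the
background plus noise, mimicking the dim non-fluorescent channels of a
filter-cube photograph.  The vignette term darkens toward the image corners.
Noise is Gaussian, seeded, and independent per channel, so identical
(field, config) pairs render to identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from .simulate import ConcentrationField

__all__ = ["RenderConfig", "ImageMetadata", "RawEyeImage", "render_image"]


@dataclass
class RenderConfig:
    """Camera parameters on the 8-bit intensity scale.

    ``gain`` converts concentration (mass per cell) to intensity counts.  The
    default is matched to the simulator's default unit bolus on a 0.1 mm grid:
    at day-scale measurement times the brightest cell stays inside the 8-bit
    range (exposure chosen to avoid clipping, as in practice), while the
    compact time-0 bolus may saturate.
    """

    gain: float = 2.0e5
    background_level: float = 20.0
    noise_sigma: float = 2.0
    vignette_strength: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0 <= self.background_level < 255:
            raise ValueError("background_level must be in [0, 255)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.vignette_strength <= 1:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")


@dataclass
class ImageMetadata:
    """Per-image provenance carried alongside the pixels."""

    eye_id: str = ""
    dye_label: str = ""
    time_h: float = 0.0
    injection_side: str = "temporal"
    model: str = "synthetic"  # e.g. ex vivo pig / in vivo pig / human / synthetic


@dataclass
class RawEyeImage:
    """An RGB photograph of one bisected-eye face plus its pixel scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_scale: float  # mm per pixel
    metadata: ImageMetadata = dataclass_field(default_factory=ImageMetadata)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")


def _vignette(shape: tuple[int, int], strength: float, background: float) -> np.ndarray:
    if strength == 0.0:
        return np.zeros(shape)
    n_rows, n_cols = shape
    r = np.arange(n_rows) - (n_rows - 1) / 2.0
    c = np.arange(n_cols) - (n_cols - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    r_corner2 = ((n_rows - 1) / 2.0) ** 2 + ((n_cols - 1) / 2.0) ** 2
    return -strength * background * (rr * rr + cc * cc) / r_corner2


def render_image(
    field: ConcentrationField,
    render: RenderConfig,
    metadata: Optional[ImageMetadata] = None,
) -> RawEyeImage:
    """Render a concentration field as an 8-bit RGB fluorescence photograph."""
    rng = np.random.default_rng(render.seed)
    shape = field.grid.shape
    vig = _vignette(shape, render.vignette_strength, render.background_level)

    def _quantize(plane: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(plane), 0, 255).astype(np.uint8)

    def _noise() -> np.ndarray:
        if render.noise_sigma == 0.0:
            return np.zeros(shape)
        return rng.normal(0.0, render.noise_sigma, size=shape)

    green = render.background_level + render.gain * field.grid + vig + _noise()
    red = render.background_level / 2.0 + _noise()
    blue = render.background_level / 2.0 + _noise()
    pixels = np.stack([_quantize(red), _quantize(green), _quantize(blue)], axis=-1)
    return RawEyeImage(
        pixels=pixels,
        pixel_scale=field.grid_spacing,
        metadata=metadata or ImageMetadata(time_h=field.time),
    )
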