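"""Fluorescent-region quantification on normalized bisected-eye images.

The measurement chain follows the photographic analysis it re-implements:
sweep a set of intensity thresholds over the eye interior, keep one
contiguous (8-connected) fluorescent region at the working threshold of 70,
express its physical area as a percentage of the circle-approximated eye
area, and summarize its extent with two radius definitions — half the
largest caliper (Feret) diameter, and the distance from the region centroid
to its farthest boundary pixel.  A nasal/temporal hemifield split and an
n-repeat reproducibility audit complete the per-eye record.

Conventions: pixel coordinates are 0-based pixel centers; distances are
between pixel centers; threshold comparison is ``>= tau`` (the stated levels
are inclusive); components use 8-connectivity, region-boundary detection
uses 4-connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

from .imaging import NormalizedImage
from .render import ImageMetadata

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SELECTED_THRESHOLD",
    "EyeBoundary",
    "FluorescenceRegion",
    "QuantResult",
    "RepeatabilityResult",
    "RepeatabilityError",
    "sweep_thresholds",
    "extract_region",
    "area_percent",
    "radius_feret",
    "radius_centroid",
    "hemifield_fractions",
    "repeatability_audit",
    "measure_eye",
    "fit_diffusivity",
]

#: Threshold sweep evaluated for every image (8-bit intensity units).
DEFAULT_THRESHOLDS: tuple[int, ...] = (30, 50, 70, 90, 120, 150, 200)
#: Working threshold used for all headline measurements.
SELECTED_THRESHOLD: int = 70


class RepeatabilityError(RuntimeError):
    """Raised when repeated automated measurements disagree beyond tolerance."""


@dataclass
class EyeBoundary:
    """Manually drawn eye outline plus the diameters derived from it.

    The overall eye size is approximated as a circle whose diameter is the
    mean of the nasal–temporal and inferior–superior diameters; its area is
    the default denominator for the fluorescent-area percentage.
    """

    polygon_xy: np.ndarray  # (N, 2) vertices, pixel units, (x, y)
    mask: np.ndarray  # boolean, image shape
    pixel_scale: float  # mm per pixel
    diameter_nt: float  # mm
    diameter_is: float  # mm

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if len(self.polygon_xy) >= 3 and not ShapelyPolygon(self.polygon_xy).is_simple:
            raise ValueError("boundary polygon must be simple (non-self-intersecting)")

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.diameter_nt + self.diameter_is)

    @property
    def circle_area(self) -> float:
        """Circle-approximated eye area, mm^2."""
        return math.pi * (self.mean_diameter / 2.0) ** 2

    @property
    def mask_area(self) -> float:
        """Polygon-mask pixel area, mm^2 (optional denominator)."""
        return float(self.mask.sum()) * self.pixel_scale**2

    @classmethod
    def from_polygon(
        cls,
        polygon_xy: Sequence[Sequence[float]],
        image_shape: tuple[int, int],
        pixel_scale: float,
        diameter_nt: Optional[float] = None,
        diameter_is: Optional[float] = None,
    ) -> "EyeBoundary":
        """Build from an annotation polygon.

        When the manual diameters are not supplied they are computed from the
        polygon extents along the image horizontal (nasal–temporal) and
        vertical (inferior–superior) axes.
        """
        poly = np.asarray(polygon_xy, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("boundary polygon needs at least 3 (x, y) vertices")
        mask = polygon2mask(image_shape, poly[:, ::-1])
        if diameter_nt is None:
            diameter_nt = float(poly[:, 0].max() - poly[:, 0].min()) * pixel_scale
        if diameter_is is None:
            diameter_is = float(poly[:, 1].max() - poly[:, 1].min()) * pixel_scale
        return cls(poly, mask, pixel_scale, diameter_nt, diameter_is)


@dataclass
class FluorescenceRegion:
    """One contiguous above-threshold region inside the eye boundary."""

    mask: np.ndarray
    threshold: int
    pixel_count: int
    centroid_xy: Optional[tuple[float, float]]  # (x, y) pixel units
    boundary_rc: np.ndarray  # (K, 2) (row, col) of 4-connected boundary pixels
    excluded_signal_fraction: float  # % of lit pixels outside the kept component

    @property
    def is_empty(self) -> bool:
        return self.pixel_count == 0


@dataclass
class QuantResult:
    """Per-eye measurement record at one threshold."""

    eye_id: str
    threshold: int
    area_percent: float
    radius_feret: Optional[float]  # mm; None when no region
    radius_centroid: Optional[float]  # mm
    nasal_fraction: Optional[float]  # % of in-region signal
    temporal_fraction: Optional[float]
    excluded_signal_fraction: float
    dye_label: str = ""
    time_h: float = 0.0
    injection_side: str = ""
    model: str = ""


@dataclass
class RepeatabilityResult:
    radii_mm: list[float]
    spread_mm: float  # max - min
    std_mm: float


def sweep_thresholds(
    image: NormalizedImage,
    boundary: EyeBoundary,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> dict[int, np.ndarray]:
    """Per-threshold raw masks (before component selection).

    For each threshold ``tau`` the mask holds pixels inside the eye boundary
    with intensity ``>= tau``.  Raw pixel counts are ``mask.sum()``.
    """
    if any(not 0 <= t <= 255 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 255]")
    return {int(t): boundary.mask & (image.pixels >= t) for t in thresholds}


def _select_component(labels: np.ndarray, n_labels: int, anchor_xy: tuple[float, float]) -> int:
    """Largest component; ties broken by centroid distance to ``anchor_xy``
    (the first boundary-polygon vertex), then by lowest row-major index."""
    sizes = ndimage.sum_labels(np.ones(labels.shape), labels, index=range(1, n_labels + 1))
    max_size = sizes.max()
    candidates = [i + 1 for i, s in enumerate(sizes) if s == max_size]
    if len(candidates) == 1:
        return candidates[0]
    ax, ay = anchor_xy

    def _key(lab: int) -> tuple[float, int]:
        rr, cc = np.nonzero(labels == lab)
        d = math.hypot(cc.mean() - ax, rr.mean() - ay)
        first = int(rr[0] * labels.shape[1] + cc[0])
        return (d, first)

    return min(candidates, key=_key)


def _region_boundary(mask: np.ndarray) -> np.ndarray:
    """(row, col) pixels of ``mask`` with at least one 4-neighbor outside."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    rr, cc = np.nonzero(mask & ~interior)
    return np.column_stack([rr, cc])


def extract_region(
    mask: np.ndarray,
    boundary: EyeBoundary,
    seed_point: Optional[tuple[int, int]] = None,
    threshold: int = SELECTED_THRESHOLD,
) -> FluorescenceRegion:
    """Keep one 8-connected component of the thresholded mask.

    The component containing ``seed_point`` (x, y) wins when given and lit;
    otherwise the largest component is kept.  The fraction of above-threshold
    pixels left outside the kept component is always reported so the policy
    is auditable.
    """
    if seed_point is not None:
        sx, sy = int(round(seed_point[0])), int(round(seed_point[1]))
        if not (0 <= sy < mask.shape[0] and 0 <= sx < mask.shape[1]) or not boundary.mask[sy, sx]:
            raise ValueError("seed point lies outside the eye boundary")
    total_lit = int(mask.sum())
    if total_lit == 0:
        return FluorescenceRegion(
            mask=np.zeros_like(mask),
            threshold=threshold,
            pixel_count=0,
            centroid_xy=None,
            boundary_rc=np.empty((0, 2), dtype=int),
            excluded_signal_fraction=0.0,
        )
    labels, n_labels = cc_label(mask, connectivity=2, return_num=True)
    chosen = 0
    if seed_point is not None and mask[sy, sx]:
        chosen = int(labels[sy, sx])
    if chosen == 0:
        anchor = tuple(boundary.polygon_xy[0]) if len(boundary.polygon_xy) else (0.0, 0.0)
        chosen = _select_component(labels, n_labels, anchor)
    region_mask = labels == chosen
    count = int(region_mask.sum())
    rr, cc = np.nonzero(region_mask)
    centroid = (float(cc.mean()), float(rr.mean()))
    return FluorescenceRegion(
        mask=region_mask,
        threshold=threshold,
        pixel_count=count,
        centroid_xy=centroid,
        boundary_rc=_region_boundary(region_mask),
        excluded_signal_fraction=100.0 * (total_lit - count) / total_lit,
    )


def area_percent(
    region: FluorescenceRegion,
    boundary: EyeBoundary,
    pixel_scale: float,
    denominator: str = "circle",
) -> float:
    """Fluorescent area as a percentage of the total eye area.

    The denominator is the circle approximation from the averaged orthogonal
    diameters by default; ``denominator="mask"`` switches to the
    polygon-mask pixel area.
    """
    if denominator == "circle":
        denom = boundary.circle_area
    elif denominator == "mask":
        denom = boundary.mask_area
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if denom <= 0:
        raise ValueError("eye area denominator is zero")
    return 100.0 * region.pixel_count * pixel_scale**2 / denom


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest Euclidean distance between any two points.

    Reduced to the convex hull for speed; equals the all-pairs maximum since
    the diameter of a point set is attained at hull vertices.
    """
    if len(points) <= 2:
        if len(points) < 2:
            return 0.0
        return float(np.hypot(*(points[0] - points[1])))
    pts = points.astype(float)
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except QhullError:  # degenerate (collinear) sets
        hull_pts = pts
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def radius_feret(region: FluorescenceRegion, pixel_scale: float) -> float:
    """Half the largest observable diameter of the region, in mm."""
    if region.is_empty:
        raise ValueError("radius is undefined for an empty region")
    rr, cc = np.nonzero(region.mask)
    pts = np.column_stack([rr, cc]).astype(float)
    return _max_pairwise_distance(pts) * pixel_scale / 2.0


def radius_centroid(region: FluorescenceRegion, pixel_scale: float) -> float:
    """Distance from the region centroid to its most distant boundary pixel, mm."""
    if region.is_empty:
        raise ValueError("radius is undefined for an empty region")
    cx, cy = region.centroid_xy
    d = np.hypot(region.boundary_rc[:, 1] - cx, region.boundary_rc[:, 0] - cy)
    return float(d.max()) * pixel_scale


def hemifield_fractions(
    region: FluorescenceRegion,
    boundary: EyeBoundary,
    nasal_side: str = "left",
) -> tuple[float, float]:
    """Percentages of region signal in the nasal and temporal hemifields.

    The split is the vertical line through the eye-boundary centroid; pixels
    exactly on the line count half to each side.  ``nasal_side`` names the
    image side ("left"/"right") that is anatomically nasal.
    """
    if region.is_empty:
        raise ValueError("hemifields are undefined for an empty region")
    if nasal_side not in ("left", "right"):
        raise ValueError("nasal_side must be 'left' or 'right'")
    _, b_cc = np.nonzero(boundary.mask)
    split_x = float(b_cc.mean()) if b_cc.size else (region.mask.shape[1] - 1) / 2.0
    _, cc = np.nonzero(region.mask)
    left = float(np.sum(cc < split_x)) + 0.5 * float(np.sum(cc == split_x))
    total = float(len(cc))
    left_pct = 100.0 * left / total
    right_pct = 100.0 - left_pct
    return (left_pct, right_pct) if nasal_side == "left" else (right_pct, left_pct)


def repeatability_audit(
    image: NormalizedImage,
    boundary: EyeBoundary,
    n_repeats: int = 8,
    threshold: int = SELECTED_THRESHOLD,
    jitter: bool = False,
) -> RepeatabilityResult:
    """Repeat the segmentation -> centroid-radius chain ``n_repeats`` times.

    The chain is deterministic, so the spread must vanish; the audit raises
    :class:`RepeatabilityError` if max - min reaches 0.001 mm.  With
    ``jitter`` the threshold is perturbed by cycling -1/0/+1 units to probe
    sensitivity instead (no assertion then).
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats")
    radii = []
    for i in range(n_repeats):
        tau = threshold + ((i % 3) - 1 if jitter else 0)
        mask = sweep_thresholds(image, boundary, [tau])[tau]
        region = extract_region(mask, boundary, threshold=tau)
        radii.append(radius_centroid(region, boundary.pixel_scale))
    spread = max(radii) - min(radii)
    if not jitter and spread >= 0.001:
        raise RepeatabilityError(f"radius spread {spread:.6f} mm exceeds 0.001 mm")
    return RepeatabilityResult(radii_mm=radii, spread_mm=spread, std_mm=float(np.std(radii)))


def measure_eye(
    image: NormalizedImage,
    boundary: EyeBoundary,
    metadata: Optional[ImageMetadata] = None,
    threshold: int = SELECTED_THRESHOLD,
    seed_point: Optional[tuple[int, int]] = None,
    nasal_side: str = "left",
    denominator: str = "circle",
) -> QuantResult:
    """Full per-eye measurement at the working threshold.

    An eye without any above-threshold signal yields area 0% with the radii
    and hemifields flagged undefined (None).
    """
    meta = metadata or ImageMetadata(eye_id=image.source)
    mask = sweep_thresholds(image, boundary, [threshold])[threshold]
    region = extract_region(mask, boundary, seed_point=seed_point, threshold=threshold)
    area = area_percent(region, boundary, boundary.pixel_scale, denominator=denominator)
    if region.is_empty:
        r_f = r_c = nasal = temporal = None
    else:
        r_f = radius_feret(region, boundary.pixel_scale)
        r_c = radius_centroid(region, boundary.pixel_scale)
        nasal, temporal = hemifield_fractions(region, boundary, nasal_side=nasal_side)
    return QuantResult(
        eye_id=meta.eye_id,
        threshold=threshold,
        area_percent=area,
        radius_feret=r_f,
        radius_centroid=r_c,
        nasal_fraction=nasal,
        temporal_fraction=temporal,
        excluded_signal_fraction=region.excluded_signal_fraction,
        dye_label=meta.dye_label,
        time_h=meta.time_h,
        injection_side=meta.injection_side,
        model=meta.model,
    )


def fit_diffusivity(
    times_h: Sequence[float],
    radii_mm: Sequence[float],
    threshold: int = SELECTED_THRESHOLD,
) -> float:
    """Estimate the diffusivity from the growth of the measured radius.

    For a Gaussian spot normalized so its peak maps to 255, the threshold
    contour at ``tau`` sits at ``r^2 = 2 * ln(255/tau) * (sigma0^2 + 2 D t)``,
    so ``r^2`` grows linearly in time with slope ``4 * ln(255/tau) * D``.
    A least-squares line through (t, r^2) therefore recovers D in mm^2/h.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(radii_mm, dtype=float)
    if t.size != r.size or t.size < 2:
        raise ValueError("need at least two (time, radius) pairs")
    if not 0 < threshold < 255:
        raise ValueError("threshold must be in (0, 255)")
    slope = np.polyfit(t, r**2, 1)[0]
    return float(slope / (4.0 * math.log(255.0 / threshold)))
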