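"""Orchestration: generate -> normalize -> quantify -> report.

Functions here are the library form of the CLI subcommands: they process
whole directories (or in-memory cohorts), append per-eye records to tidy
tables, and write a manifest describing every run (config hash, package
version, seeds, input checksums) so runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort import CohortEye, disc_boundary_polygon, generate_cohort, write_cohort
from .imaging import (
    Annotation,
    BackgroundRegion,
    extract_green_channel,
    load_annotation,
    normalize,
    read_image,
    subtract_background,
)
from .quantify import (
    DEFAULT_THRESHOLDS,
    SELECTED_THRESHOLD,
    EyeBoundary,
    QuantResult,
    area_percent,
    extract_region,
    measure_eye,
    sweep_thresholds,
)
from .render import ImageMetadata
from .stats import cohort_report

logger = logging.getLogger(__name__)

__all__ = [
    "QUANT_COLUMNS",
    "run_simulate",
    "process_image_file",
    "run_quantify",
    "measure_cohort",
    "run_report",
    "write_manifest",
]

QUANT_COLUMNS = [
    "eye_id",
    "model",
    "dye_label",
    "time_h",
    "side",
    "threshold",
    "area_percent",
    "radius_feret_mm",
    "radius_centroid_mm",
    "nasal_pct",
    "temporal_pct",
    "excluded_pct",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Union[str, Path], config: dict, inputs: Sequence[Path] = ()) -> Path:
    """Write a run manifest (config hash, version, input checksums)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def run_simulate(
    preset: str,
    n_eyes: int,
    seed: int,
    out_dir: Union[str, Path],
    times: Optional[Sequence[float]] = None,
    grid_spacing: Optional[float] = None,
    presets_path: Optional[Union[str, Path]] = None,
) -> dict:
    """Generate a cohort and write images, annotations and ground truth."""
    eyes = generate_cohort(
        preset, n_eyes, seed, times=times, presets_path=presets_path, grid_spacing=grid_spacing
    )
    manifest = write_cohort(eyes, out_dir)
    write_manifest(
        out_dir,
        {
            "command": "simulate",
            "preset": preset,
            "n_eyes": n_eyes,
            "seed": seed,
            "times": list(times) if times is not None else None,
            "grid_spacing": grid_spacing,
        },
    )
    return manifest


def _result_row(result: QuantResult) -> dict:
    return {
        "eye_id": result.eye_id,
        "model": result.model,
        "dye_label": result.dye_label,
        "time_h": result.time_h,
        "side": result.injection_side,
        "threshold": result.threshold,
        "area_percent": result.area_percent,
        "radius_feret_mm": result.radius_feret,
        "radius_centroid_mm": result.radius_centroid,
        "nasal_pct": result.nasal_fraction,
        "temporal_pct": result.temporal_fraction,
        "excluded_pct": result.excluded_signal_fraction,
    }


def process_image_file(
    image_path: Union[str, Path],
    annotation_path: Union[str, Path],
    threshold: int = SELECTED_THRESHOLD,
    denominator: str = "circle",
) -> QuantResult:
    """Normalize and measure one photograph with its JSON annotation."""
    ann_raw = json.loads(Path(annotation_path).read_text())
    pixel_scale = ann_raw.get("pixel_scale_mm")
    if pixel_scale is None:
        raise ValueError(f"annotation {annotation_path} lacks pixel_scale_mm")
    meta = ImageMetadata(
        eye_id=Path(image_path).stem,
        dye_label=ann_raw.get("dye_label", ""),
        time_h=float(ann_raw.get("time_h", 0.0)),
        injection_side=ann_raw.get("injection_side", ""),
        model=ann_raw.get("model", ""),
    )
    raw = read_image(image_path, pixel_scale=pixel_scale, metadata=meta)
    ann = load_annotation(annotation_path, raw.pixels.shape[:2])
    green = extract_green_channel(raw)
    if ann.background is not None:
        subtracted, estimate = subtract_background(green, ann.background)
    else:
        subtracted, estimate = green.astype(float), 0.0
        logger.warning("no background region for %s; skipping subtraction", image_path)
    normalized = normalize(subtracted, source=meta.eye_id, background_estimate=estimate)
    boundary = EyeBoundary.from_polygon(
        ann.boundary_xy,
        normalized.pixels.shape,
        pixel_scale=pixel_scale,
        diameter_nt=ann.diameter_nt_mm,
        diameter_is=ann.diameter_is_mm,
    )
    seed_point = None
    if ann.seed_point_xy is not None:
        seed_point = (int(round(ann.seed_point_xy[0])), int(round(ann.seed_point_xy[1])))
    return measure_eye(
        normalized,
        boundary,
        metadata=meta,
        threshold=threshold,
        seed_point=seed_point,
        nasal_side=ann.nasal_side,
        denominator=denominator,
    )


def run_quantify(
    images_dir: Union[str, Path],
    annotations_dir: Union[str, Path],
    out_csv: Union[str, Path],
    threshold: int = SELECTED_THRESHOLD,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    denominator: str = "circle",
    write_sweep: bool = False,
) -> dict:
    """Measure every annotated image in a directory; returns a summary.

    Images without a matching annotation are skipped with a warning (the run
    still succeeds); skipped stems are listed in the returned summary.
    """
    images_dir, annotations_dir = Path(images_dir), Path(annotations_dir)
    image_paths = sorted(p for p in images_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not image_paths:
        raise FileNotFoundError(f"no images found in {images_dir}")
    rows, sweep_rows, skipped = [], [], []
    for img_path in image_paths:
        ann_path = annotations_dir / f"{img_path.stem}.json"
        if not ann_path.exists():
            logger.warning("no annotation for %s; skipped", img_path.name)
            skipped.append(img_path.stem)
            continue
        result = process_image_file(img_path, ann_path, threshold=threshold, denominator=denominator)
        rows.append(_result_row(result))
        if write_sweep:
            ann_raw = json.loads(ann_path.read_text())
            meta = ImageMetadata(eye_id=img_path.stem)
            raw = read_image(img_path, pixel_scale=ann_raw["pixel_scale_mm"], metadata=meta)
            ann = load_annotation(ann_path, raw.pixels.shape[:2])
            green = extract_green_channel(raw)
            if ann.background is not None:
                green, _ = subtract_background(green, ann.background)
            norm = normalize(green, source=img_path.stem)
            boundary = EyeBoundary.from_polygon(
                ann.boundary_xy, norm.pixels.shape, ann_raw["pixel_scale_mm"],
                diameter_nt=ann.diameter_nt_mm, diameter_is=ann.diameter_is_mm,
            )
            for tau, mask in sweep_thresholds(norm, boundary, thresholds).items():
                region = extract_region(mask, boundary, threshold=tau)
                sweep_rows.append(
                    {
                        "eye_id": img_path.stem,
                        "threshold": tau,
                        "raw_pixel_count": int(mask.sum()),
                        "area_percent": area_percent(region, boundary, boundary.pixel_scale, denominator),
                    }
                )
    df = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    if write_sweep and sweep_rows:
        pd.DataFrame(sweep_rows).to_csv(out_csv.with_name(out_csv.stem + "_sweep.csv"), index=False)
    write_manifest(
        out_csv.parent,
        {"command": "quantify", "threshold": threshold, "denominator": denominator},
        inputs=image_paths,
    )
    return {"quant_csv": str(out_csv), "n_measured": len(rows), "skipped": skipped}


def measure_cohort(eyes: Sequence[CohortEye], threshold: int = SELECTED_THRESHOLD) -> pd.DataFrame:
    """Measure an in-memory synthetic cohort (no disk round-trip).

    Applies the identical chain used for files: green channel, corner
    background subtraction, min-max normalization, boundary from the true
    disc geometry, threshold segmentation and all per-eye metrics.
    """
    rows = []
    for eye in eyes:
        green = extract_green_channel(eye.image)
        background = BackgroundRegion.from_rect(green.shape, 2, 2, 12, 12)
        subtracted, estimate = subtract_background(green, background)
        norm = normalize(subtracted, source=eye.truth["eye_id"], background_estimate=estimate)
        boundary = EyeBoundary.from_polygon(
            disc_boundary_polygon(eye.config),
            green.shape,
            pixel_scale=eye.config.grid_spacing,
            diameter_nt=eye.config.eye_diameter,
            diameter_is=eye.config.eye_diameter,
        )
        result = measure_eye(norm, boundary, metadata=eye.image.metadata, threshold=threshold)
        rows.append(_result_row(result))
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def run_report(
    quant_csv: Union[str, Path],
    out_dir: Union[str, Path],
    measure: str = "area_percent",
) -> dict:
    """Group statistics + bar-chart data for a quantification table."""
    quant_csv = Path(quant_csv)
    df = pd.read_csv(quant_csv)
    if df.empty:
        raise ValueError(f"quantification table {quant_csv} is empty")
    report = cohort_report(df, measure=measure, out_dir=out_dir)
    write_manifest(out_dir, {"command": "report", "measure": measure}, inputs=[quant_csv])
    return report
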