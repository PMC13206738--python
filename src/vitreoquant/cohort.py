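"""Ground-truthed synthetic cohorts mirroring the four study arms.

Each preset (``ex_vivo_5dye``, ``in_vivo_2dye``, ``plasmin``,
``human_bursa``) draws per-eye globe diameters from the recorded range of
its model, simulates hindered diffusion of each dye in the panel, renders a
noisy photograph, and keeps the full ground truth (true diffusivity, side,
occluder geometry, true above-threshold area) so every downstream
measurement can be validated.  Presets live in a YAML file inside the
package and can be overridden by a user-supplied file of the same shape.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field as dataclass_field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import yaml
from shapely.geometry import Polygon as ShapelyPolygon

from .dyes import DYE_CATALOG, DyeSpec, stokes_einstein_diffusivity
from .quantify import SELECTED_THRESHOLD
from .render import ImageMetadata, RawEyeImage, RenderConfig, render_image
from .simulate import ConcentrationField, SimulationConfig, initialize_bolus, simulate_diffusion

__all__ = [
    "ScenarioError",
    "CohortEye",
    "load_presets",
    "generate_cohort",
    "write_cohort",
    "disc_boundary_polygon",
]


class ScenarioError(ValueError):
    """Unknown preset name or malformed preset configuration."""


@dataclass
class CohortEye:
    """One synthetic eye: rendered image, simulation state, ground truth."""

    image: RawEyeImage
    field: ConcentrationField
    config: SimulationConfig
    truth: dict


def load_presets(path: Optional[Union[str, Path]] = None) -> dict:
    """Load the scenario presets (packaged YAML, or an override file)."""
    if path is None:
        text = resources.files("vitreoquant").joinpath("data/presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "presets" not in data:
        raise ScenarioError("preset file must define a 'presets' mapping")
    return data


def _bursa_polygon(spec: dict, radius_mm: float) -> list[tuple[float, float]]:
    cx = spec["center_frac"][0] * radius_mm
    cy = spec["center_frac"][1] * radius_mm
    r = spec["radius_frac"] * radius_mm
    n = int(spec.get("n_vertices", 16))
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in ang]


def disc_boundary_polygon(config: SimulationConfig, n_vertices: int = 128) -> np.ndarray:
    """(x, y) pixel-coordinate polygon of the true disc boundary."""
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    xs = config.radius * np.cos(ang)
    ys = config.radius * np.sin(ang)
    pts = [config.mm_to_pixel(x, y) for x, y in zip(xs, ys)]
    return np.array([(c, r) for r, c in pts])


def _true_area_percent(field: ConcentrationField, config: SimulationConfig, threshold: int) -> float:
    """Area fraction of the eye above the normalized working threshold.

    With the background removed and the peak mapped to 255, the threshold at
    ``tau`` intensity units selects cells with ``C >= (tau/255) * Cmax``.
    """
    cmax = field.grid.max()
    if cmax <= 0:
        return 0.0
    n_above = int(np.sum(field.grid >= (threshold / 255.0) * cmax))
    eye_area = math.pi * config.radius**2
    return 100.0 * n_above * config.grid_spacing**2 / eye_area


def generate_cohort(
    scenario: str,
    n_eyes: int,
    seed: int,
    times: Optional[Sequence[float]] = None,
    presets_path: Optional[Union[str, Path]] = None,
    grid_spacing: Optional[float] = None,
) -> list[CohortEye]:
    """Generate ``n_eyes`` per dye-by-time group of the named scenario.

    Identical (scenario, n_eyes, seed) calls produce byte-identical images.
    ``times`` restricts the preset's time points (e.g. only 24 h);
    ``grid_spacing`` overrides the preset resolution.
    """
    if n_eyes < 1:
        raise ScenarioError("n_eyes must be >= 1")
    data = load_presets(presets_path)
    presets = data["presets"]
    if scenario not in presets:
        raise ScenarioError(f"unknown preset {scenario!r}; available: {sorted(presets)}")
    defaults = data.get("defaults", {})
    spec = {**defaults, **presets[scenario]}
    render_spec = {**defaults.get("render", {}), **presets[scenario].get("render", {})}
    use_times = list(times) if times is not None else [float(t) for t in spec["times"]]
    unknown_times = set(use_times) - {float(t) for t in spec["times"]}
    if times is not None and unknown_times:
        raise ScenarioError(f"times {sorted(unknown_times)} not part of preset {scenario!r}")
    mesh = float(spec["mesh_size"]) * float(spec.get("mesh_multiplier", 1.0))
    dx = float(grid_spacing) if grid_spacing is not None else float(spec["grid_spacing"])

    rng = np.random.default_rng(seed)
    eyes: list[CohortEye] = []
    for dye_label in spec["dyes"]:
        dye = DYE_CATALOG[dye_label]
        for time_h in use_times:
            for i in range(n_eyes):
                diameter = float(rng.uniform(*spec["diameter_range"]))
                if spec.get("randomize_side", False):
                    side = str(rng.choice(["nasal", "temporal"]))
                else:
                    side = spec.get("side", "temporal")
                sim_seed = int(rng.integers(2**31))
                render_seed = int(rng.integers(2**31))
                occluders = []
                if "bursa" in spec:
                    occluders.append(_bursa_polygon(spec["bursa"], diameter / 2.0))
                config = SimulationConfig(
                    eye_diameter=diameter,
                    grid_spacing=dx,
                    injection_offset=float(spec["injection_offset"]),
                    injection_side=side,
                    needle_depth=float(spec["needle_depth"]),
                    bolus_sigma=float(spec["bolus_sigma"]),
                    bolus_mass=float(spec["bolus_mass"]),
                    temperature=float(spec["temperature"]),
                    viscosity=float(spec["viscosity"]),
                    mesh_size=mesh,
                    duration=time_h,
                    output_times=[time_h],
                    occluders=occluders,
                    padding=float(spec["padding"]),
                    seed=sim_seed,
                )
                d_eff = stokes_einstein_diffusivity(dye, config)
                field0 = initialize_bolus(config, dye)
                field = simulate_diffusion(field0, d_eff, config)[0]
                eye_id = f"{scenario}_{dye_label.replace(' ', '')}_{int(time_h)}h_{i:02d}"
                meta = ImageMetadata(
                    eye_id=eye_id,
                    dye_label=dye_label,
                    time_h=time_h,
                    injection_side=side,
                    model=spec["model"],
                )
                image = render_image(field, RenderConfig(seed=render_seed, **render_spec), meta)
                truth = {
                    "eye_id": eye_id,
                    "preset": scenario,
                    "dye_label": dye_label,
                    "stokes_radius_nm": dye.stokes_radius,
                    "D_eff_mm2_per_h": d_eff,
                    "eye_diameter_mm": diameter,
                    "injection_side": side,
                    "time_h": time_h,
                    "bolus_mass": config.bolus_mass,
                    "seed": sim_seed,
                    "occluder_wkt": ShapelyPolygon(occluders[0]).wkt if occluders else "",
                    "true_area_percent_tau70": _true_area_percent(field, config, SELECTED_THRESHOLD),
                }
                eyes.append(CohortEye(image=image, field=field, config=config, truth=truth))
    return eyes


_TRUTH_COLUMNS = [
    "eye_id",
    "preset",
    "dye_label",
    "stokes_radius_nm",
    "D_eff_mm2_per_h",
    "eye_diameter_mm",
    "injection_side",
    "time_h",
    "bolus_mass",
    "seed",
    "occluder_wkt",
    "true_area_percent_tau70",
]


def write_cohort(eyes: Sequence[CohortEye], out_dir: Union[str, Path]) -> dict:
    """Write images (PNG), annotations (JSON), ground truth (CSV + JSON).

    The boundary annotation is derived from the true disc geometry: a
    128-gon of the disc outline, the true diameter for both orthogonal
    diameters, and a fluorescence-free corner rectangle as the background
    region.  Returns a manifest of written paths.
    """
    out = Path(out_dir)
    images_dir = out / "images"
    ann_dir = out / "annotations"
    images_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for eye in eyes:
        eye_id = eye.truth["eye_id"]
        iio.imwrite(images_dir / f"{eye_id}.png", eye.image.pixels)
        annotation = {
            "boundary": disc_boundary_polygon(eye.config).tolist(),
            "background": {"rect": [2, 2, 12, 12]},
            "nasal_side": "left",
            "diameter_nt_mm": eye.config.eye_diameter,
            "diameter_is_mm": eye.config.eye_diameter,
            "pixel_scale_mm": eye.config.grid_spacing,
            "dye_label": eye.truth["dye_label"],
            "time_h": eye.truth["time_h"],
            "injection_side": eye.truth["injection_side"],
            "model": eye.image.metadata.model,
        }
        with open(ann_dir / f"{eye_id}.json", "w") as fh:
            json.dump(annotation, fh)
        rows.append({k: eye.truth[k] for k in _TRUTH_COLUMNS})

    truth_csv = out / "truth.csv"
    with open(truth_csv, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TRUTH_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    sidecar = out / "cohort_config.json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "n_eyes": len(eyes),
                "presets": [e.truth["preset"] for e in eyes[:1]],
                "grid_spacing": eyes[0].config.grid_spacing if eyes else None,
            },
            fh,
            indent=2,
        )
    return {
        "images_dir": str(images_dir),
        "annotations_dir": str(ann_dir),
        "truth_csv": str(truth_csv),
        "config_json": str(sidecar),
        "n_images": len(eyes),
    }
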