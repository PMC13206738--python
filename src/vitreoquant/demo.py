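"""Deterministic demo eye, generated at run time from a frozen configuration.

Images are never shipped; this module rebuilds the same synthetic photograph
(byte-identical for a given seed) whenever the demo fixture is needed, and
the measurement chain applied to it is therefore reproducible exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import disc_boundary_polygon
from .dyes import DYE_CATALOG, stokes_einstein_diffusivity
from .imaging import BackgroundRegion, NormalizedImage, extract_green_channel, normalize, subtract_background
from .quantify import EyeBoundary
from .render import ImageMetadata, RawEyeImage, RenderConfig, render_image
from .simulate import SimulationConfig, initialize_bolus, simulate_diffusion

__all__ = ["DemoEye", "make_demo_eye", "DEMO_SEED"]

DEMO_SEED = 20240501


@dataclass
class DemoEye:
    raw: RawEyeImage
    normalized: NormalizedImage
    boundary: EyeBoundary
    config: SimulationConfig
    diffusivity: float


def make_demo_eye(seed: int = DEMO_SEED, dye_label: str = "40 kDa", time_h: float = 24.0) -> DemoEye:
    """One synthetic ex-vivo-style eye, simulated, rendered and normalized.

    A 22 mm eye at 4 °C with a temporal injection; the dye and observation
    time are configurable.  The same seed reproduces the same image bytes.
    """
    config = SimulationConfig(
        eye_diameter=22.0,
        grid_spacing=0.1,
        injection_side="temporal",
        temperature=277.15,
        mesh_size=20.0,
        duration=time_h,
        output_times=[time_h],
        seed=seed,
    )
    dye = DYE_CATALOG[dye_label]
    d_eff = stokes_einstein_diffusivity(dye, config)
    field = simulate_diffusion(initialize_bolus(config, dye), d_eff, config)[0]
    meta = ImageMetadata(
        eye_id=f"demo_{dye_label.replace(' ', '')}_{int(time_h)}h",
        dye_label=dye_label,
        time_h=time_h,
        injection_side="temporal",
        model="synthetic demo",
    )
    raw = render_image(field, RenderConfig(seed=seed), meta)
    green = extract_green_channel(raw)
    background = BackgroundRegion.from_rect(green.shape, 2, 2, 12, 12)
    subtracted, estimate = subtract_background(green, background)
    normalized = normalize(subtracted, source=meta.eye_id, background_estimate=estimate)
    boundary = EyeBoundary.from_polygon(
        disc_boundary_polygon(config),
        green.shape,
        pixel_scale=config.grid_spacing,
        diameter_nt=config.eye_diameter,
        diameter_is=config.eye_diameter,
    )
    return DemoEye(raw=raw, normalized=normalized, boundary=boundary, config=config, diffusivity=d_eff)
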