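import json
from pathlib import Path

import numpy as np
import pytest

from vitreoquant.cohort import generate_cohort
from vitreoquant.demo import make_demo_eye
from vitreoquant.quantify import EyeBoundary

DATA_DIR = Path(__file__).parent / "data"

#: Seeds are fixed study conditions of the synthetic experiments.
COHORT_SEED = 1


@pytest.fixture(scope="session")
def demo_eye():
    """The packaged deterministic demo eye (40 kDa, 24 h, fixed seed)."""
    return make_demo_eye()


@pytest.fixture(scope="session")
def cohort_24h():
    """Seeded 5-dye ex-vivo cohort, n=8 per dye, observed at 24 h."""
    return generate_cohort("ex_vivo_5dye", 8, seed=COHORT_SEED, times=[24.0])


@pytest.fixture(scope="session")
def cohort_full():
    """Seeded 5-dye ex-vivo cohort at both time points (coarser grid)."""
    return generate_cohort("ex_vivo_5dye", 8, seed=COHORT_SEED, grid_spacing=0.15)


@pytest.fixture(scope="session")
def golden_quant():
    with open(DATA_DIR / "golden_demo_quant.json") as fh:
        return json.load(fh)


@pytest.fixture
def full_frame_boundary():
    """An EyeBoundary covering an entire image, for mask-level unit tests."""

    def _make(shape, pixel_scale=1.0):
        h, w = shape
        poly = np.array([[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]])
        return EyeBoundary(
            polygon_xy=poly,
            mask=np.ones(shape, dtype=bool),
            pixel_scale=pixel_scale,
            diameter_nt=w * pixel_scale,
            diameter_is=h * pixel_scale,
        )

    return _make
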