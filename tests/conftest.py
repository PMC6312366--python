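import logging
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pollinet import (
    ExperimentDesign,
    LandscapeGrid,
    default_community,
    generate_surface,
    make_gradient,
)
from pollinet.experiments import run_experiment

# degenerate-habitat placement warnings are expected in many tests
logging.getLogger("pollinet").setLevel(logging.ERROR)
logging.getLogger("pollinet.simulator").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def community():
    """Default 20-bee / 20-flower community with seed-0 diets."""
    return default_community(seed=0)


@pytest.fixture(scope="session")
def half_cover_grid():
    """A generated 50%-cover fractal landscape (H = 0.9)."""
    surface = generate_surface(0.9, seed=5)
    return make_gradient(surface, [0.5]).grids[0]


@pytest.fixture()
def checkerboard_grid():
    cover = np.indices((10, 10)).sum(axis=0) % 2
    return LandscapeGrid(cover=cover.astype(np.int8))


@pytest.fixture(scope="session")
def full_experiment():
    """The full default design: 11 cover levels x 10 replicates.

    Session-scoped because several structural checks (H2' bounds, GLM
    trend directions, diet closure) all read the same 110-run table.
    """
    design = ExperimentDesign(base_seed=5)
    return design, run_experiment(design)
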