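from pathlib import Path

import pytest

from stimchip import synthetic
from stimchip.io import load_chamber_config

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def chamber_config():
    return load_chamber_config(REPO_ROOT / "examples" / "chamber_example.yaml")


@pytest.fixture(scope="session")
def default_movie():
    """One reference-condition synthetic movie (128x128, 1000 frames,
    30 cells, sigma = 5 counts), shared across tests that only read it."""
    return synthetic.simulate_movie(seed=7)


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.MovieSpec(height=48, width=48, n_frames=200)
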