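import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from satscribe.simulate import PlantedSatelliteSpec, default_scene, random_unit, simulate_genome


@pytest.fixture(scope="session")
def small_scene():
    """Default synthetic study at reduced read depth, shared across tests."""
    return default_scene(seed=42, reads_per_sample=300)


@pytest.fixture(scope="session")
def planted_perfect():
    """One perfect 6 x 45-nt array in 10 kb of background, with truth."""
    rng = np.random.default_rng(0)
    unit = random_unit(rng, 45)
    spec = PlantedSatelliteSpec("chr1", 2000, unit, 6)
    genome, genes, truth = simulate_genome([spec], 10_000, seed=5)
    return genome, truth
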