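import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from digibreak.simulate import PlantedFamily, SimConfig, make_genome, simulate_breaks


def random_genome(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def asisi_sim():
    """Small AsiSI simulation: genome, planted sites and per-cell truth."""
    cfg = SimConfig(
        genome_length=60_000,
        seed=11,
        n_cells=300,
        background_rate=1.0,
        planted_sites=[PlantedFamily("GCGATCGC", 8, chemistry="asisi_3prime_overhang")],
    )
    genome, sites = make_genome(cfg)
    truth = simulate_breaks(cfg, sites)
    return cfg, genome, sites, truth
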