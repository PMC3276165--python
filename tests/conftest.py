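import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from surimpute import HaplotypePanel, VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_panel(rng, n_sites=50, n_haps=20, spacing=1000):
    positions = np.cumsum(rng.integers(1, spacing, size=n_sites))
    sites = [VariantSite(f"rs{j}", int(positions[j]), "A", "C")
             for j in range(n_sites)]
    alleles = rng.integers(0, 2, size=(n_sites, n_haps)).astype(np.uint8)
    return HaplotypePanel(sites=sites, alleles=alleles)


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)
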