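import numpy as np
import pytest

from cdpmine.mining import PipelineConfig
from cdpmine.residues import residue_library
from cdpmine.simulate import FixtureSpec, PlantedCompound, generate_network


@pytest.fixture(scope="session")
def library():
    return residue_library()


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def pro_trio_bundle():
    """Three Pro-containing CDPs; all-pairwise edges via shared Pro ions."""
    spec = FixtureSpec(
        compounds=(
            PlantedCompound(("Val", "Pro"), 12.71),
            PlantedCompound(("Ala", "Pro"), 5.05),
            PlantedCompound(("Leu", "Pro"), 18.79),
        ),
        seed=11,
        ppm_sigma=2.0,
    )
    return generate_network(spec)


def rng(seed=0):
    return np.random.default_rng(seed)
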