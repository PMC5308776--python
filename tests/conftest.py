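import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from oriscan.example_loci import synthetic_ars305, synthetic_ars607
from oriscan.simulate import (PlantedElement, SyntheticSpec, generate_dataset,
                              random_study_spec)


@pytest.fixture(scope="session")
def ars607():
    return synthetic_ars607()


@pytest.fixture(scope="session")
def ars305():
    return synthetic_ars305()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact matched triple: 3 chromosomes, a handful of planted pairs."""
    planted = [
        PlantedElement("chr1", 5_000, "divergent", 72, with_acs=True,
                       with_atrack=True, at_peak=True),
        PlantedElement("chr1", 20_000, "convergent", 65, at_peak=False),
        PlantedElement("chr2", 9_000, "unidirectional", 88, at_peak=True),
        PlantedElement("chr2", 30_000, "divergent", 75, at_peak=False),
    ]
    spec = SyntheticSpec(chrom_lengths=[50_000, 50_000, 40_000],
                         planted=planted, seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def study_dataset():
    """A mid-size study: planted pairs across all orientation x gap classes."""
    return generate_dataset(random_study_spec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
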