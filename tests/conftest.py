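import numpy as np
import pytest

from alemut.io_formats import CdsFeature, ReferenceGenome
from alemut.simulate import SimulationConfig, generate_reference


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    """Small, fast study configuration shared across tests."""
    return SimulationConfig(genome_length=30_000, seed=11, n_lineages=2,
                            generations_total=1000, sampling_interval=200,
                            n_preexisting_snvs=15, coverage_mean=100,
                            background_sites=20)


@pytest.fixture(scope="session")
def small_genome(desk_config) -> ReferenceGenome:
    return generate_reference(desk_config)


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    """60 bp genome with one '+' CDS and one '-' CDS, hand-checkable.

    forward CDS 1..15:  ATG GGA ATT CAT TAA
    reverse CDS 31..45: genome-forward TTA ATG AAT TCC CAT reads on '-'
                        strand as ATG GGA ATT CAT TAA as well.
    """
    fwd = "ATGGGAATTCATTAA"
    rev = "TTAATGAATTCCCAT"
    filler1 = "ACGTACGTACGTACG"  # 16..30
    filler2 = "CATGCATGCATGCAT"  # 46..60
    seq = fwd + filler1 + rev + filler2
    feats = [CdsFeature("plus_gene", 1, 15, "+"),
             CdsFeature("minus_gene", 31, 45, "-")]
    return ReferenceGenome(id="toy", sequence=seq, features=feats)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
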