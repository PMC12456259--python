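import numpy as np
import pytest

from metaprotdb.config import Config
from metaprotdb.synthetic import CommunitySpec, gen_community


@pytest.fixture(scope="session")
def config():
    return Config()


@pytest.fixture(scope="session")
def fast_config():
    """Sketching at low scaled so tiny fixtures keep enough hashes."""
    return Config(scaled=50)


@pytest.fixture(scope="session")
def community():
    """Small three-sample community with a planted+novel catalogue."""
    spec = CommunitySpec(
        n_samples=3,
        n_genomes=5,
        genes_per_genome=30,
        genome_length_bp=40_000,
        n_catalogue_planted=2,
        n_catalogue_novel=2,
        seed=11,
    )
    return gen_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
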