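import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture()
def toy():
    """Default synthetic harmonic pair (k_bond=10, k_siteA=10, k_siteB=40)."""
    from atswap.synthetic import make_toy_pair

    return make_toy_pair(seed=0)


@pytest.fixture()
def toy_system(toy):
    from atswap.pipeline import make_system

    structure, partition, model, restraints = toy
    return make_system(structure, partition, model, restraints)


@pytest.fixture()
def tiam1_network():
    import atswap
    from atswap.io import read_network

    return read_network(atswap.packaged_data("tiam1_pdz_edges.tsv"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
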