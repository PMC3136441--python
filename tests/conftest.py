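import pytest

from junctionmech import build_reference, load_catalog, simulate_mechanism_panel


@pytest.fixture(scope="session")
def ref():
    genome = build_reference(seed=1)
    genome.kmer_index()  # warm the seed index once for the whole session
    return genome


@pytest.fixture(scope="session")
def records():
    return load_catalog()


@pytest.fixture(scope="session")
def panel_noiseless(ref):
    return simulate_mechanism_panel(ref, per_mechanism=100, seed_start=1)


@pytest.fixture(scope="session")
def panel_noisy(ref):
    return simulate_mechanism_panel(ref, per_mechanism=100, seed_start=1, read_noise=0.005)
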