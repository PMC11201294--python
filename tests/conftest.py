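import pytest

from syntherm import load_motif_rules, load_reactions, load_species_table
from syntherm.simulate import BatchSimParams


@pytest.fixture(scope="session")
def species_table():
    return load_species_table()


@pytest.fixture(scope="session")
def reactions():
    return load_reactions()


@pytest.fixture(scope="session")
def motif_rules():
    return load_motif_rules()


@pytest.fixture()
def noiseless_params():
    defaults = BatchSimParams()
    return BatchSimParams(seed=1, noise_sd={k: 0.0 for k in defaults.noise_sd})
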