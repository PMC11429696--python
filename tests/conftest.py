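import pytest

from gazevote.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def study_sim():
    """One full study-design simulation (273 races, 3 monkeys x 2 days)."""
    return simulate_dataset(SimConfig(seed=101))


@pytest.fixture(scope="session")
def study_data_dir(tmp_path_factory, study_sim):
    """The same simulation written to disk in the interchange schemas."""
    d = tmp_path_factory.mktemp("study_data")
    study_sim.write(d)
    return d
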