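import pytest

from famdiverge import synthetic_data as sim


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset (seed 7, default preset) shared by the suite."""
    return sim.simulate_dataset(sim.default_config(7))


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    """The same dataset written to disk in its file dialects."""
    out = tmp_path_factory.mktemp("sim")
    default_dataset.write(out)
    return out
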