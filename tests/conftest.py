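import pytest

from teislands import SimulationParams, simulate_dataset
from teislands.synthetic import write_dataset


def small_params(seed: int = 7) -> SimulationParams:
    """A reduced genome (2 x 600 kb, one planted island) for fast tests."""
    return SimulationParams(
        seed=seed,
        n_scaffolds=2,
        scaffold_length=600_000,
        n_islands=1,
        island_length_range=(120_000, 160_000),
        n_duplications=3,
    )


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_params())


@pytest.fixture(scope="session")
def small_report(small_dataset):
    from teislands import analyze_dataset

    return analyze_dataset(small_dataset)


@pytest.fixture(scope="session")
def dataset_dir(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    write_dataset(small_dataset, outdir)
    return outdir
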