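import pytest

from traptag.junctions import FinderParams
from traptag.synthetic import SyntheticConfig, simulate_dataset


def small_config(**overrides) -> SyntheticConfig:
    """A fast, reduced-scale screen for unit tests."""
    base = dict(seed=7, n_scaffolds=2, scaffold_length=120_000, n_genes=8,
                n_insertions_per_construct=3, n_read_pairs=400,
                chimera_fraction=0.05)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def dataset():
    """Full-scale synthetic screen shared across the suite (fixed seed)."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def reporter(dataset):
    return dataset.elements["non_IRES"].reporter_orf


@pytest.fixture(scope="session")
def finder_params(dataset):
    return FinderParams(ires_tag=dataset.elements["IRES"].ires_tag)


@pytest.fixture(scope="session")
def truth_chimeric_ids(dataset):
    ids = set()
    for s in dataset.truth["chimeric_read_ids"]:
        ids.update(i for i in str(s).split(",") if i)
    return ids
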