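import logging

import pytest

from phosphodrug import syndata

logging.getLogger("phosphodrug").setLevel(logging.ERROR)


def small_sim_config(seed: int = 1, **overrides) -> syndata.SimConfig:
    """A reduced-scale config that still carries every planted structure."""
    base = dict(
        n_cell_lines=30,
        n_proteins=150,
        n_psites=120,
        n_pathways=4,
        pathway_size=6,
        n_kinases=4,
        substrates_per_kinase=3,
        n_outliers=3,
        n_drugs=8,
        n_planted_markers_per_drug=3,
        n_differential_features=16,
        module_size=16,
        seed=seed,
    )
    base.update(overrides)
    return syndata.SimConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default-scale dataset (60 cell lines), seed 1."""
    return syndata.generate_dataset(syndata.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return syndata.generate_dataset(small_sim_config())


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_dataset")
    syndata.write_dataset(out, small_sim_config())
    return out
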