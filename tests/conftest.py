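"""Shared fixtures: one default synthetic study per session plus derived objects."""

import pytest

from magsnv.matrix import filter_sites
from magsnv.simulate import SimulationConfig, simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def default_study():
    """The default-condition synthetic study (36 animals, 3 days, 6 MAGs)."""
    return simulate_study(SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The same study written to disk in the external file dialects."""
    out = tmp_path_factory.mktemp("study")
    simulate_study(SimulationConfig(seed=STUDY_SEED), out_dir=out)
    return out


@pytest.fixture(scope="session")
def study_matrix(default_study):
    return default_study.to_matrix()


@pytest.fixture(scope="session")
def study_geno(study_matrix):
    return filter_sites(study_matrix)
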