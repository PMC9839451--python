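import pytest

from spurcatch import GeneModel, PipelineParams, SimConfig
from spurcatch.synthetic_data import simulate_cage, simulate_chip, simulate_genome


@pytest.fixture
def params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel.from_genomic_exons(
        "plus", "chr1", "+", [(0, 100), (200, 300), (400, 500)])


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel.from_genomic_exons(
        "minus", "chr1", "-", [(0, 100), (200, 300), (400, 500)])


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # 150 genes on 3 chromosomes: big enough for tier statistics, small
    # enough that every module test stays fast
    return SimConfig(n_genes=150, seed=17)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_cage(small_config, small_sim):
    return simulate_cage(small_config, small_sim)


@pytest.fixture(scope="session")
def small_chip(small_config, small_sim):
    return simulate_chip(small_config, small_sim)
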