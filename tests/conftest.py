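import pytest

from snopipe.simulate import (
    SimulationConfig,
    make_genome,
    simulate_clip_reads,
    simulate_srna_reads,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_genome(sim_config):
    return make_genome(sim_config)


@pytest.fixture(scope="session")
def sim_truths(sim_genome):
    return sim_genome[1]


@pytest.fixture(scope="session")
def sim_annotations(sim_truths):
    return [t.annotation() for t in sim_truths]


@pytest.fixture(scope="session")
def clip_library(sim_genome, sim_config):
    genome, truths = sim_genome
    return simulate_clip_reads(truths, genome, sim_config, "clipA", stream=1)


@pytest.fixture(scope="session")
def clip_replicate(sim_genome, sim_config):
    genome, truths = sim_genome
    return simulate_clip_reads(truths, genome, sim_config, "clipB", stream=11)


@pytest.fixture(scope="session")
def long_srna_library(sim_truths, sim_config):
    return simulate_srna_reads(sim_truths, sim_config, "long", stream=2)


@pytest.fixture(scope="session")
def short_srna_library(sim_truths, sim_config):
    return simulate_srna_reads(sim_truths, sim_config, "short", stream=5)
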