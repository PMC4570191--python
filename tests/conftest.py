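import pytest

from mirflow import clean_reads, collapse
from mirflow.simulate import SimulationConfig, simulate_libraries


@pytest.fixture(scope="session")
def sim_dataset():
    """A moderate two-library simulation shared across tests."""
    cfg = SimulationConfig(seed=11, depth_per_library=20_000)
    return simulate_libraries(cfg)


@pytest.fixture(scope="session")
def sim_tags(sim_dataset):
    cfg = sim_dataset.config
    clean_vs, stats_vs = clean_reads(sim_dataset.reads_vs, cfg.adapter5, cfg.adapter3)
    clean_rs, stats_rs = clean_reads(sim_dataset.reads_rs, cfg.adapter5, cfg.adapter3)
    tags = collapse(clean_vs, clean_rs)
    return {
        "tags": tags,
        "stats_vs": stats_vs,
        "stats_rs": stats_rs,
        "clean_vs": clean_vs,
        "clean_rs": clean_rs,
    }
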