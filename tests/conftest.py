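import pytest

from panphylo.pipeline import PipelineResult, run_pipeline
from panphylo.synthetic_data import SimConfig, SimResult, simulate


@pytest.fixture(scope="session")
def concordant_run() -> tuple[SimResult, PipelineResult]:
    """50 groups, no gene-tree discordance, 20% truncated isoforms."""
    cfg = SimConfig(n_genes=50, discord_rate=0.0, truncation_prob=0.2, seed=1)
    data = simulate(cfg)
    return data, run_pipeline(data)


@pytest.fixture(scope="session")
def discordant_run() -> tuple[SimResult, PipelineResult]:
    """Same conditions with 30% of gene trees one NNI away from the species tree."""
    cfg = SimConfig(n_genes=50, discord_rate=0.3, truncation_prob=0.2, seed=1)
    data = simulate(cfg)
    return data, run_pipeline(data)


@pytest.fixture(scope="session")
def default_200_run() -> tuple[SimResult, PipelineResult]:
    """The default synthetic dataset: 200 genes, default divergence, seed 1."""
    cfg = SimConfig(n_genes=200, seed=1)
    data = simulate(cfg)
    return data, run_pipeline(data)
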