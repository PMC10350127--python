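import pytest
from hypothesis import settings

from lnctar.pipeline import PipelineConfig, run_pipeline
from lnctar.simulate import SimConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def small_sim_config(seed: int = 5, **overrides) -> SimConfig:
    """A fast, fully featured simulation config for unit tests."""
    params = dict(
        seed=seed,
        n_mrna=60,
        n_lncrna=30,
        n_chrom=3,
        chrom_length=3_000_000,
        n_de_genes=12,
        n_cis_pairs=3,
        n_trans_pairs=3,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def default_run():
    """One full-pipeline run at the default study conditions (seed 1)."""
    return run_pipeline(PipelineConfig(sim=SimConfig(seed=1)))


@pytest.fixture()
def small_cfg():
    return small_sim_config()
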