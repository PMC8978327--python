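import pytest

from bcellcerna.synthetic_data import SimulationConfig, generate_dataset

#: Small study sized so every planted role fits each layer; used wherever a
#: full tri-omics dataset is needed.
SMALL_KWARGS = dict(
    n_circ=300, n_mirna=100, n_mrna=200,
    n_planted_triplets=3, n_planted_de=6, n_planted_patterns=2,
)


@pytest.fixture(scope="session")
def hard_dataset():
    """Deterministic (hard-planted) dataset plus its ground truth."""
    cfg = SimulationConfig(hard_planting=True, rng_seed=11, **SMALL_KWARGS)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Poisson-sampled dataset plus its ground truth."""
    cfg = SimulationConfig(rng_seed=7, **SMALL_KWARGS)
    return generate_dataset(cfg)
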