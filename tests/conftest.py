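import numpy as np
import pytest

from gxenet.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny end-to-end dataset shared across tests (session-scoped: read-only)."""
    cfg = SimConfig(
        n_hybrids=60, n_snps=120, n_envs=10, missing_rate=0.02,
        n_constant_cols=8, n_duplicate_pairs=4,
        season_length_range=(30, 40), years=(2019, 2020, 2021),
        effect_variances={"additive_g": 1.0, "additive_e": 0.6,
                          "interaction": 0.4, "noise": 0.2},
        seed=42,
    )
    return cfg, simulate_dataset(cfg)
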