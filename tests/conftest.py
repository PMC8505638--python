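import numpy as np
import pytest

from fedhe import mhe
from fedhe.protocol import DataProvider, setup_collaboration
from fedhe.simulate import GwasSimConfig, gen_gwas, split_gwas


@pytest.fixture
def small_params():
    return mhe.CryptoParams(num_slots=64, depth_budget=5, precision_bits=40, mode="exact")


@pytest.fixture
def collab3(small_params):
    return setup_collaboration(["dp0", "dp1", "dp2"], params=small_params, seed=11)


@pytest.fixture(scope="session")
def gwas_cohort():
    """Shared synthetic cohort: p=800, f=12, v=64 (kept small for speed)."""
    ds, truth = gen_gwas(GwasSimConfig(p=800, f=12, v=64, seed=42))
    return ds, truth


def make_dps(ds, k, seed=0):
    return [DataProvider(f"dp{i}", s) for i, s in enumerate(split_gwas(ds, k, seed=seed))]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
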