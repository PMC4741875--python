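import numpy as np
import pandas as pd
import pytest

from cpgvar.synth import SynthConfig, generate_snp_panel


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=11, n_snps=4000, chrom_length=1_000_000)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_snp_panel(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_proxies(n: int, seed: int) -> pd.DataFrame:
    """Covariate-only proxy panel used by several enrichment tests."""
    from cpgvar.synth import generate_proxy_covariates

    return generate_proxy_covariates(n, seed=seed)
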