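import numpy as np
import pytest

from rktumor.params import InteractionParams, PhenotypeParams


@pytest.fixture
def pr_small() -> PhenotypeParams:
    """r-type phenotype at a small, fast-to-simulate scale."""
    return PhenotypeParams(
        label="r", intrinsic_rate=0.05, carrying_capacity=500.0, baseline_death=0.01
    )


@pytest.fixture
def pk_small() -> PhenotypeParams:
    return PhenotypeParams(
        label="K", intrinsic_rate=0.03, carrying_capacity=1000.0, baseline_death=0.005
    )


@pytest.fixture
def no_interaction() -> InteractionParams:
    return InteractionParams(0.0, 0.0)


@pytest.fixture
def fitted_interaction() -> InteractionParams:
    """The best-supported interaction: K cells crowd r cells, not vice versa."""
    return InteractionParams(2.2, 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
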