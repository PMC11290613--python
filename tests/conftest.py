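import numpy as np
import pytest

from survcontour.data import SurvivalDataset
from survcontour.synthetic import SimSpec, gen_competing, gen_ph_weibull


@pytest.fixture
def tiny_right_censored() -> SurvivalDataset:
    """Four subjects, hand-checkable: times 1..4, last one censored."""
    return SurvivalDataset.from_arrays(
        times=[1.0, 2.0, 3.0, 4.0],
        events=[1, 1, 1, 0],
        predictor=[1.0, 0.0, 1.0, 0.0],
    )


@pytest.fixture
def ph_dataset() -> SurvivalDataset:
    return gen_ph_weibull(SimSpec(n=200, beta=(0.7,), censoring_rate=0.3, seed=11))


@pytest.fixture
def competing_dataset() -> SurvivalDataset:
    return gen_competing(
        SimSpec(n=250, beta=(0.5,), p_cause1=0.4, censoring_rate=0.2, seed=21)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
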