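import pandas as pd
import pytest

from clozerep.epochs import EpochSet
from clozerep.generator import GeneratorParams, make_design, simulate_epochs
from helpers import constant_epochs


@pytest.fixture(scope="session")
def tiny_params() -> GeneratorParams:
    """Small but fully crossed design: 2 labs x 4 subjects x 12 items."""
    return GeneratorParams(
        n_labs=2,
        subjects_per_lab=4,
        n_items=12,
        n_control_items=8,
        noise_sd=3.0,
        sd_trial=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_design(tiny_params) -> pd.DataFrame:
    return make_design(tiny_params)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_params, tiny_design) -> EpochSet:
    return simulate_epochs(tiny_design, tiny_params)


@pytest.fixture
def flat_epochs() -> EpochSet:
    return constant_epochs(0.0)
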