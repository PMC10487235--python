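import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ribofis as rf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return rf.build_variables()


@pytest.fixture(scope="session")
def order_preserving_rules():
    def make(factor):
        return [rf.Rule({factor: label}, label) for label in ("low", "medium", "high")]

    return make


@pytest.fixture(scope="session")
def casamino_model(order_preserving_rules):
    return rf.build_single_factor_model("casamino", order_preserving_rules("casamino"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230822)
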