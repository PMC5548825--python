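import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from cllcea import base_parameter_set, evaluate_strategies

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_ps():
    """The documented default (noise-free) parameter set."""
    return base_parameter_set()


@pytest.fixture(scope="session")
def base_results(base_ps):
    """All five strategies evaluated on the default set."""
    return evaluate_strategies(base_ps)


@pytest.fixture()
def all_fixed(base_ps):
    """The default set with every parameter's PSA distribution disabled."""
    params = {
        name: dataclasses.replace(p, distribution="fixed")
        for name, p in base_ps.parameters.items()
    }
    return dataclasses.replace(base_ps, parameters=params)
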