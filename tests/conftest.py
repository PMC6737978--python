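import pytest

from msicd import (
    DamageParams,
    PlatenGeometry,
    ViscoelasticModel,
    compute_rates,
    simulate_study,
    summarize,
)


@pytest.fixture(scope="session")
def geom():
    return PlatenGeometry()


@pytest.fixture(scope="session")
def model():
    return ViscoelasticModel()


@pytest.fixture(scope="session")
def params():
    return DamageParams()


@pytest.fixture(scope="session")
def exp1_table(params, geom, model):
    return simulate_study(1, params=params, geom=geom, model=model, seed=1234)


@pytest.fixture(scope="session")
def exp1_summary(exp1_table):
    return summarize(compute_rates(exp1_table))
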