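import pytest

from erygem import Medium, SyntheticSpec, make_toy_model


@pytest.fixture(scope="session")
def toy():
    """Default toy erythromycin-producer network and its analytic ground truth."""
    return make_toy_model(SyntheticSpec())


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def ground_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def glucose_medium():
    """Sole-carbon glucose minimal medium at the default uptake bound."""
    return Medium(sole_carbon=True, bounds={"EX_glc__D_e": (-10.0, 1000.0)})


@pytest.fixture()
def fresh_toy():
    """A mutable copy for tests that edit the network."""
    model, truth = make_toy_model(SyntheticSpec())
    return model, truth
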