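import pytest

from fbarebalance import (
    AdjustmentConfig,
    Measurement,
    MeasurementSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelParams,
    extract_biomass_spec,
    make_toy_model,
)


@pytest.fixture(scope="session")
def toy_model():
    """Default toy model: 3 components, GAM 10, glucose uptake 10."""
    return make_toy_model(ToyModelParams(seed=0))


@pytest.fixture(scope="session")
def toy_spec_gam(toy_model):
    return extract_biomass_spec(toy_model)


@pytest.fixture()
def chain_model():
    """Two-reaction chain: rA produces A, rB consumes it (r_A = r_B)."""
    return MetabolicModel(
        metabolites=[Metabolite("A", compartment="c")],
        reactions=[
            Reaction("rA", {"A": 1.0}, -10.0, 10.0),
            Reaction("rB", {"A": -1.0}, -10.0, 10.0),
        ],
        objective={"rB": 1.0},
        biomass_reaction_id="rB",
    )


@pytest.fixture()
def chain_measurements():
    """Inconsistent chain measurements: r_A = 2, r_B = 1 with equal weights."""
    return MeasurementSet(
        {"rA": Measurement(2.0, sd=1.0), "rB": Measurement(1.0, sd=1.0)}
    )


@pytest.fixture()
def flux_qp_config():
    return AdjustmentConfig(mode="qp", adjust_fluxes=True)
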