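import pytest

from tubigem import MetabolicModel, Metabolite, Reaction, ToySpec, make_toy_model

#: default toy-model medium (exchange id -> max uptake, mmol gDW^-1 h^-1)
TOY_MEDIUM = {
    "EX_glc__D_e": 10.0, "EX_pi_e": 10.0, "EX_nh4_e": 10.0,
    "EX_o2_e": 20.0, "EX_h2o_e": 1000.0, "EX_h_e": 1000.0,
}

#: toy FBA optimum on the default glucose medium, frozen from two
#: independent LP routes (scipy HiGHS and GLPK agree to < 1e-12)
TOY_GROWTH_OPTIMUM = 1.3598568547836347


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_model_decoys() -> MetabolicModel:
    return make_toy_model(ToySpec(n_decoy_deadends=3))


@pytest.fixture()
def chain_model() -> MetabolicModel:
    """A -> B -> C with an exchange only for A; C is a dead end."""
    mets = [Metabolite(id=f"{x}_c", compartment="c") for x in "BC"]
    mets.append(Metabolite(id="A_e", compartment="e"))
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A_e": -1}, lower_bound=-10),
        Reaction(id="R1", stoichiometry={"A_e": -1, "B_c": 1}),
        Reaction(id="R2", stoichiometry={"B_c": -1, "C_c": 1}),
    ]
    return MetabolicModel(id="chain", metabolites=mets, reactions=rxns)
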