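import numpy as np
import pytest

from gluconet import (MetabolicModel, Metabolite, Reaction, StudyConfig,
                      KineticParams, make_toy_network)

# Table of published human gluconokinase kinetic properties used as
# input throughout the kinetics tests: (Km uM, Vmax uM/s, kcat 1/s)
GLUCONATE_KM = 106.4
GLUCONATE_VMAX = 2.3
ATP_KM = 343.8
ATP_KCAT = 9.5
ENZYME_CONC = 0.25  # uM


@pytest.fixture(scope="session")
def chain_model() -> MetabolicModel:
    """Three-reaction uptake chain: EX_A -> R1 -> EX_B, maximize R1."""
    return MetabolicModel(
        metabolites=[Metabolite("A_c", compartment="c"),
                     Metabolite("B_c", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A_c": -1}, -1.0, 0.0),
            Reaction("R1", {"A_c": -1, "B_c": 1}, 0.0, 1000.0),
            Reaction("EX_B", {"B_c": -1}, 0.0, 1000.0),
        ],
        objective={"R1": 1.0},
        id="chain",
    )


@pytest.fixture(scope="session")
def mini_model() -> MetabolicModel:
    """Seven-reaction branched network with all-finite bounds.

    Substrate A can be converted through a high-capacity route (one ATP
    per unit) or a capped route (two ATP per unit); the ATP-consuming
    pump is the objective. Small enough for exhaustive vertex
    enumeration: optimum = 1.5*1 + 0.5*2 = 2.5.
    """
    return MetabolicModel(
        metabolites=[Metabolite(i, compartment="c")
                     for i in ("A_c", "B_c", "C_c", "D_c", "atp_c", "adp_c")],
        reactions=[
            Reaction("EX_A", {"A_c": -1}, -2.0, 0.0),
            Reaction("R_AB", {"A_c": -1, "B_c": 1}, 0.0, 10.0),
            Reaction("R_AC", {"A_c": -1, "C_c": 1}, 0.0, 0.5),
            Reaction("R_B", {"B_c": -1, "adp_c": -1, "D_c": 1, "atp_c": 1},
                     0.0, 10.0),
            Reaction("R_C", {"C_c": -1, "adp_c": -2, "D_c": 1, "atp_c": 2},
                     0.0, 10.0),
            Reaction("PUMP", {"atp_c": -1, "adp_c": 1}, 0.0, 10.0),
            Reaction("EX_D", {"D_c": -1}, 0.0, 10.0),
        ],
        objective={"PUMP": 1.0},
        id="mini_branched",
    )


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_config() -> StudyConfig:
    # sweep covers the toy-scale plateau and collapse
    return StudyConfig(sweep_grid=tuple(np.round(np.arange(0, 1.2001, 0.02), 3)))


@pytest.fixture(scope="session")
def gluconate_params() -> KineticParams:
    return KineticParams.from_km_vmax(GLUCONATE_KM, GLUCONATE_VMAX,
                                      ENZYME_CONC)
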