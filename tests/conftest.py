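import numpy as np
import pytest

from efmcost import (
    ConstraintSet,
    KineticModel,
    MetabolicNetwork,
    ReactionKinetics,
    SaturationSpec,
    build_lactis_model,
    build_overflow_model,
)


@pytest.fixture(scope="session")
def chain_network() -> MetabolicNetwork:
    """S_ext -> A -> (objective)."""
    return MetabolicNetwork(
        metabolite_ids=("S", "A"),
        is_external={"S": True, "A": False},
        stoichiometry=np.array([[-1.0, 0.0], [1.0, -1.0]]),
        reaction_ids=("uptake", "objective"),
        objective_index=1,
    )


@pytest.fixture(scope="session")
def diamond_network() -> MetabolicNetwork:
    """Two parallel routes S_ext -> A, then A -> (objective)."""
    return MetabolicNetwork(
        metabolite_ids=("S", "A"),
        is_external={"S": True, "A": False},
        stoichiometry=np.array([[-1.0, -1.0, 0.0], [1.0, 1.0, -1.0]]),
        reaction_ids=("route_1", "route_2", "objective"),
        objective_index=2,
    )


@pytest.fixture(scope="session")
def chain_model(chain_network) -> KineticModel:
    """Two-step chain with MM kinetics and a single total-enzyme pool."""
    kinetics = {
        "uptake": ReactionKinetics(
            kcat=3.0,
            saturation=SaturationSpec(
                kind="michaelis_menten", substrate_ids=("S",), Km={"S": 1.0}
            ),
        ),
        "objective": ReactionKinetics(
            kcat=2.0,
            saturation=SaturationSpec(
                kind="michaelis_menten", substrate_ids=("A",), Km={"A": 1.0}
            ),
        ),
    }
    constraints = ConstraintSet(
        weights=np.array([[1.0, 1.0]]), bounds=np.array([1.0]), pool_ids=("total",)
    )
    return KineticModel(network=chain_network, kinetics=kinetics, constraints=constraints)


@pytest.fixture(scope="session")
def overflow_model() -> KineticModel:
    return build_overflow_model()


@pytest.fixture(scope="session")
def lactis_model() -> KineticModel:
    return build_lactis_model()
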