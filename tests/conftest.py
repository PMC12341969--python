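import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxmark import MetabolicModel, Metabolite, Reaction, make_toy_network

settings.register_profile(
    "fluxmark",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("fluxmark")


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_network()


@pytest.fixture()
def chain_model():
    """EX_A (uptake <= 1) -> A -> B -> demand; demand is the objective."""
    return MetabolicModel(
        metabolites=[Metabolite("A[c]"), Metabolite("B[c]")],
        reactions=[
            Reaction("EX_A", {"A[c]": -1.0}, lower_bound=-1.0, upper_bound=0.0),
            Reaction("A2B", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0, gpr="g1"),
            Reaction("DM_B", {"B[c]": -1.0}, 0.0, 1000.0),
        ],
        genes=["g1"],
        objective_id="DM_B",
    )


@pytest.fixture()
def diamond_model():
    """A -> B via r1 or r2 (each capacity 1), demand fixed at 1."""
    return MetabolicModel(
        metabolites=[Metabolite("A[c]"), Metabolite("B[c]")],
        reactions=[
            Reaction("EX_A", {"A[c]": -1.0}, -2.0, 0.0),
            Reaction("r1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1.0),
            Reaction("r2", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1.0),
            Reaction("DM_B", {"B[c]": -1.0}, 1.0, 1.0),
        ],
        objective_id="DM_B",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def model_from_arrays(S, lb, ub, objective_index) -> tuple[MetabolicModel, str]:
    """Build a MetabolicModel from a dense stoichiometric system."""
    m, n = S.shape
    mets = [Metabolite(f"m{i}[c]") for i in range(m)]
    rxns = [
        Reaction(
            f"r{j}",
            {f"m{i}[c]": float(S[i, j]) for i in range(m) if S[i, j] != 0},
            float(lb[j]),
            float(ub[j]),
        )
        for j in range(n)
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective_id=f"r{objective_index}")
    return model, f"r{objective_index}"
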