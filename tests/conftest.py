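"""Shared fixtures: hand-analysable single-pathway model and the toy network."""

import pytest

from protalloc.model import (
    CatalyzedReaction,
    Environment,
    MEModel,
    ProteinSpec,
    RibosomeSpec,
)
from protalloc.synthetic import ToyModelConfig, batch_environment, make_toy_model


def single_pathway_model(
    kcat: float = 10.0,
    kappa: float = 20.0,
    budget: float = 0.1,
    demand_coeff: float = 1.0,
) -> MEModel:
    """One uptake enzyme, one ribosome, one dummy — solvable by hand.

    With unit molecular weights, enzyme/ribosome length 2 and precursor
    demand c, the growth optimum solves
    ``mw1*(mu*c/k) + mw_r*(mu^2*c*L1/k)/(kappa - mu*L_r) = Phi``.
    """
    return MEModel(
        metabolites=("S", "P"),
        proteins=(
            ProteinSpec("E1", mw=1.0, length=2),
            ProteinSpec("ribosome", mw=1.0, length=2),
            ProteinSpec("unmodeled", mw=1.0, length=2, is_dummy=True),
        ),
        reactions=(
            CatalyzedReaction("EX_S", {"S": 1.0}, is_exchange=True, element_tag="C"),
            CatalyzedReaction("R1", {"S": -1.0, "P": demand_coeff}, {"E1": kcat}),
            CatalyzedReaction("BIOMASS", {"P": -1.0}),
        ),
        ribosome=RibosomeSpec("ribosome", kappa=kappa),
        proteome_budget=budget,
        biomass_reaction="BIOMASS",
        id="single-pathway",
    )


def single_pathway_mu_max(
    kcat: float = 10.0, kappa: float = 20.0, budget: float = 0.1
) -> float:
    """Closed-form growth optimum of the single-pathway model.

    Independent algebraic oracle.  With e1 = mu/k and the ribosome balance
    e_r = 2*mu^2 / (k*(kappa - 2*mu)), the budget equality
    ``e1 + e_r = Phi`` multiplied through by ``k*(kappa - 2*mu)`` gives
    ``mu*kappa + 2*Phi*k*mu = Phi*k*kappa`` (the quadratic terms cancel
    for unit weights and length 2), hence the closed form below.
    """
    return budget * kcat * kappa / (kappa + 2 * budget * kcat)


@pytest.fixture(scope="session")
def toy1() -> MEModel:
    return single_pathway_model()


@pytest.fixture(scope="session")
def toy1_env() -> Environment:
    return Environment("substrate", {"EX_S"})


@pytest.fixture(scope="session")
def toy_config() -> ToyModelConfig:
    return ToyModelConfig()


@pytest.fixture(scope="session")
def toy_model(toy_config) -> MEModel:
    return make_toy_model(toy_config)


@pytest.fixture(scope="session")
def base_env(toy_model) -> Environment:
    return batch_environment(toy_model, "c1", "n1")
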