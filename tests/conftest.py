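import numpy as np
import pytest

from sdf_cea import load_default_parameters
from sdf_cea.parameters import (
    EconomicSettings,
    ModelParameters,
    StrategyTransitions,
    TransitionProbabilities,
)
from sdf_cea.synthetic import attach_psa_specs, generate_parameter_set


@pytest.fixture(scope="session")
def default_params():
    """The packaged synthetic calibrated fixture."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def generated_params():
    """A reproducible synthetic parameter set with interior probabilities."""
    return generate_parameter_set(seed=11)


def make_params(
    p_init=0.68,
    p_inc_nat=0.1,
    sdf=(0.05, 0.01, 0.5, 0.1),
    naf=(0.15, 0.02, 0.0, 0.4),
    **settings,
):
    """Hand-rolled parameter set: arm tuples are (p_incidence_tx,
    p_extract_nocaries, p_arrest, p_extract_caries)."""
    keys = ("p_incidence_tx", "p_extract_nocaries", "p_arrest", "p_extract_caries")
    return ModelParameters(
        transition=TransitionProbabilities(
            p_init_caries=p_init,
            p_incidence_nat=p_inc_nat,
            sdf=StrategyTransitions(**dict(zip(keys, sdf))),
            naf=StrategyTransitions(**dict(zip(keys, naf))),
        ),
        settings=EconomicSettings(**settings),
    )


@pytest.fixture
def simple_params():
    return make_params()


def random_occupancy(rng: np.random.Generator) -> np.ndarray:
    occ = rng.dirichlet(np.ones(5))
    return occ / occ.sum()
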