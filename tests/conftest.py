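import pytest
from hypothesis import settings

# Property tests run derandomised so results are identical on every machine.
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from antescreen import default_parameters
from antescreen import psa as psa_mod
from antescreen import tree


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_arms(params):
    return tree.evaluate_all(params)


@pytest.fixture(scope="session")
def psa_draws(params):
    """One 5000-iteration PSA shared by the stochastic summaries."""
    return psa_mod.run_psa(params, n_iterations=5000, seed=1)


# Arm means as printed in the published comparison table (QALYs, £),
# used as fixed inputs when testing reporting conventions.
PRINTED_ARMS = {
    "epds": (0.7304, 1799.0),
    "whooley": (0.7302, 1772.0),
    "whooley_epds": (0.7301, 1748.0),
    "no_screen": (0.7255, 1765.0),
}


@pytest.fixture(scope="session")
def printed_arms():
    return [tree.ArmResult(s, q, c) for s, (q, c) in PRINTED_ARMS.items()]
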