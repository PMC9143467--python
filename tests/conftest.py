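import pytest

from mitocomp.simulate import SimParams, simulate


@pytest.fixture(scope="session")
def sim4():
    """Four simulated records on a random tree, with ground truth."""
    return simulate(SimParams(n_taxa=4, seed=11))


@pytest.fixture(scope="session")
def sim_default():
    """Default-parameter simulation (15.6 kb, A+T target 70.5%)."""
    return simulate(SimParams(n_taxa=2, seed=7))
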