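import pytest

from poolscreen import simulate as sim


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen shared by read-only tests."""
    params = sim.SimScreenParams(n_shrna=400, depth=200_000, seed=11)
    return sim.simulate_screen(params)


@pytest.fixture(scope="session")
def default_screen():
    """One full-size screen at the default study conditions."""
    return sim.simulate_screen(sim.SimScreenParams(seed=5))
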