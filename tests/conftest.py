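import numpy as np
import pytest

from mibikinetics import KineticParameters, get_scenario, simulate_closed_form


@pytest.fixture(scope="session")
def fig6a_params() -> KineticParameters:
    return get_scenario("fig6a").params


@pytest.fixture(scope="session")
def fig6b_params() -> KineticParameters:
    return get_scenario("fig6b").params


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    return np.round(np.arange(0, 8.0001, 0.01), 10)


@pytest.fixture(scope="session")
def fig6a_trajectory(fig6a_params, fine_grid):
    return simulate_closed_form(fig6a_params, fine_grid)


def random_params(rng: np.random.Generator, rate_high: float = 2.0) -> KineticParameters:
    """Random nonnegative parameter draw for property sweeps."""
    r = rng.uniform(0.0, rate_high, size=6)
    return KineticParameters(
        lambda_decay=r[0], elim=r[1], beta_zx=r[2], beta_zy=r[3], beta_xz=r[4], beta_yz=r[5]
    )
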