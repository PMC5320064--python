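import numpy as np
import pytest

from coferm.model import FermentState, MonodParams, simulate


@pytest.fixture(scope="session")
def std_params() -> MonodParams:
    """A mid-range parameter set used across tests."""
    return MonodParams(
        mu_max_glc=0.5, mu_max_xyl=0.2, mu_max_ara=0.15,
        K_S_glc=2.0, K_S_xyl=1.0, K_S_ara=1.0,
        Y_XS_glc=0.08, Y_XS_xyl=0.08, Y_XS_ara=0.08,
        K_rep=1.0, K_L=2.0, P_max=90.0, n_P=1.0,
    )


@pytest.fixture(scope="session")
def single_sugar_run(std_params):
    """Noise-free glucose-only run with identifiable kinetics."""
    init = FermentState(0.0, 0.05, 20.0, 0.0, 0.0, 0.0, 0.0)
    t_grid = np.arange(0.0, 16.01, 0.5)
    traj = simulate(std_params, init, t_grid)
    return {"params": std_params, "init": init, "t_grid": t_grid,
            "observed": traj.data.copy()}


def random_params(rng) -> MonodParams:
    """Random but physically plausible parameter draw."""
    return MonodParams(
        mu_max_glc=rng.uniform(0.2, 0.8),
        mu_max_xyl=rng.uniform(0.1, 0.4),
        mu_max_ara=rng.uniform(0.05, 0.3),
        K_S_glc=rng.uniform(0.2, 3.0),
        K_S_xyl=rng.uniform(0.2, 3.0),
        K_S_ara=rng.uniform(0.2, 3.0),
        Y_XS_glc=rng.uniform(0.04, 0.15),
        Y_XS_xyl=rng.uniform(0.04, 0.15),
        Y_XS_ara=rng.uniform(0.04, 0.15),
        K_rep=rng.uniform(0.2, 5.0),
        K_L=rng.uniform(0.3, 5.0),
        P_max=rng.uniform(50.0, 120.0),
        n_P=rng.uniform(0.5, 2.0),
        alpha_glc=rng.uniform(0.0, 12.0),
        alpha_xyl=rng.uniform(0.0, 12.0),
        alpha_ara=rng.uniform(0.0, 12.0),
        beta_LP=rng.uniform(0.0, 0.03),
    )
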