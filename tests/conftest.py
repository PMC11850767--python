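import numpy as np
import pytest

from compete_dynamics import rslds, synthetic_data


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic_data.SimConfig(
        n_states=3, n_latent=2, n_units=20, n_timesteps=800, seed=7)


@pytest.fixture(scope="session")
def rotational_session(small_cfg):
    """One simulated rotational session shared across tests."""
    params = synthetic_data.make_rotational_params(small_cfg)
    latents, rates, gt = synthetic_data.simulate_session(params, small_cfg)
    return {"params": params, "latents": latents, "rates": rates, "gt": gt,
            "cfg": small_cfg}


@pytest.fixture(scope="session")
def fitted_session(rotational_session):
    """A fitted model on the shared session (expensive; fit once)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fr = rslds.fit(rotational_session["rates"], K=3, D=2, seed=7,
                       max_iter=120)
    return fr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
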