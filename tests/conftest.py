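import numpy as np
import pytest

from tanmix import GeneratorConfig, fit_fgbmle, sim_gmm_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def gmm1d_scenario():
    """Shared 1-D bimodal latent-mixture sample (modes at -3 and +3)."""
    return sim_gmm_scenario(500, 1, seed=0)


@pytest.fixture(scope="session")
def gmm1d_fit(gmm1d_scenario):
    """One fitted two-stage model on the 1-D bimodal scenario, reused widely."""
    cfg = GeneratorConfig(
        hidden_layers=(128, 64), n_candidates=20, epochs=300,
        ensemble_size=50, seed=7,
    )
    s = gmm1d_scenario
    return fit_fgbmle(s.x, s.observation_model, cfg)
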