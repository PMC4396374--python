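import numpy as np
import pytest

from shhadapt import ModelVariant, default_prior, load_fig7_parameters, run_abc_smc


@pytest.fixture(scope="session")
def fig7_params():
    return load_fig7_parameters()


@pytest.fixture(scope="session")
def gli_stability_prior():
    return default_prior(ModelVariant.GLI_STABILITY)


@pytest.fixture(scope="session")
def gli_stability_run(gli_stability_prior):
    """One reduced SMC run on the Gli-stability variant, shared by the
    inference and acceptance tests (64 particles, fixed seed)."""
    populations = run_abc_smc(
        ModelVariant.GLI_STABILITY,
        prior=gli_stability_prior,
        n_particles=64,
        seed=1,
        max_simulations=20_000,
    )
    return populations


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
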