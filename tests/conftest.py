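import warnings

import numpy as np
import pytest

import allospeed as ap
from allospeed.exceptions import ConvergenceWarning

# Seeds for the shared fixtures; fixed so the expensive fits are reproducible
# across test sessions.
DATASET_SEED = 101
MCMC_SEED = 101


@pytest.fixture(scope="session")
def reference_params():
    return ap.reference_parameters()


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset with the default empirical-emulation layout
    (699 records, hump-shaped truth)."""
    return ap.generate_dataset(ap.default_empirical_emulation(seed=DATASET_SEED))


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """The hump-shaped model fitted to the default dataset with the full
    MCMC protocol; shared across tests because it is the expensive step."""
    return ap.fit(ap.ModelSpec(), default_dataset, mcmc=ap.McmcConfig(seed=MCMC_SEED))


@pytest.fixture()
def light_mcmc():
    """Shortened sampler protocol for tests that only need rough posteriors."""
    return ap.McmcConfig(chains=2, warmup_iterations=700, sampling_iterations=1000, seed=7)


@pytest.fixture(autouse=True)
def _tolerate_convergence_warnings():
    """Shortened MCMC runs legitimately warn; tests assert on diagnostics
    explicitly where convergence matters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


def make_single_mode_config(n=40, seed=0, sigma=0.3, mode=ap.LocomotionMode.RUNNING):
    """Small single-mode simulation used by tests that want few parameters."""
    params = ap.reference_parameters(sigma=sigma)
    return ap.SimulationConfig(
        true_spec=ap.ModelSpec(),
        true_params=params,
        n_per_mode={mode: n},
        mass_range_log10={mode: (-6.0, 4.0)},
        seed=seed,
    )
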