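import numpy as np
import pytest

from ripenmr import models, synth


@pytest.fixture(scope="session")
def inst():
    return models.InstrumentSpec()


@pytest.fixture(scope="session")
def cpmg_scheme():
    return synth.default_scheme("cpmg")


@pytest.fixture(scope="session")
def satrec_scheme():
    return synth.default_scheme("satrec_cpmg")


@pytest.fixture(scope="session")
def ste_scheme():
    return synth.default_scheme("ste_cpmg")


@pytest.fixture(scope="session")
def day1_mixture():
    """Day-1 soft-centre ground truth (W/P/F1/F2 pools)."""
    return synth.default_component_table(1, 5e-3)


@pytest.fixture(scope="session")
def t2_mixture():
    """Three-pool mixture at the observed 1D T2 positions (10/30/100 ms)."""
    return synth.day1_t2_mixture()


@pytest.fixture
def make_noisy_train():
    """Factory: noiseless forward signal plus seeded Gaussian noise."""

    def _make(mixture, scheme, target_snr=500.0, seed=0):
        clean = models.forward_signal(mixture, scheme)
        sigma = synth.noise_sigma_for_snr(target_snr, mixture, scheme)
        rng = np.random.default_rng(seed)
        return models.EchoTrain(
            scheme=scheme,
            values=clean.values + rng.normal(0.0, sigma, scheme.shape),
            noise_sigma=sigma)

    return _make
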