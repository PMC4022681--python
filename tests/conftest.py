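import numpy as np
import pytest

from t1rhomap import PhantomSpec, PrepCluster, fit_t1rho, make_phantom, simulate_tsl_series

KNEE_TSLS = [0.0, 10.0, 20.0, 30.0, 40.0]
ZONE_TRUTH = {1: 35.0, 2: 45.0, 3: 55.0}  # deep, middle, superficial (ms)


@pytest.fixture(scope="session")
def phantom_snr90():
    """Worst-case-SNR phantom: compensated prep, 0±30 Hz residual B0, B1rel 1.0±0.1."""
    spec = PhantomSpec(base_snr=90.0, seed=11)
    mask, t1rho_true, b0, b1 = make_phantom(spec)
    series = simulate_tsl_series(spec, PrepCluster(mode="compensated"), tsl_list=KNEE_TSLS)
    return spec, mask, t1rho_true, b0, b1, series


@pytest.fixture(scope="session")
def fitted_snr90(phantom_snr90):
    spec, mask, t1rho_true, b0, b1, series = phantom_snr90
    return mask, t1rho_true, fit_t1rho(series, mask, method="linearized")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
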