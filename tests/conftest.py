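import numpy as np
import pytest

from harmonet import synthetic


@pytest.fixture(scope="session")
def small_template():
    return synthetic.make_template((32, 32, 8), n_tracts=2, seed=7)


@pytest.fixture(scope="session")
def quiet_covariates():
    """Covariate model with every random effect switched off."""
    return synthetic.CovariateModel(beta_age=0.0, beta_sex=0.0,
                                    subject_sd=0.0, noise_sd=0.0)


def finite_difference(f, arr, eps=1e-6):
    """Central finite-difference gradient of scalar f() w.r.t. arr in place."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        f1 = f()
        arr[i] = orig - eps
        f2 = f()
        arr[i] = orig
        g[i] = (f1 - f2) / (2 * eps)
    return g
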