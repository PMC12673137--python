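import numpy as np
import pytest

import phenoswitch as ps


@pytest.fixture(scope="session")
def params_A():
    return ps.default_params_A()


@pytest.fixture(scope="session")
def params_N():
    return ps.default_params_N()


@pytest.fixture(scope="session")
def params_2d():
    return ps.default_params_2d()


@pytest.fixture(scope="session")
def repeated_72h():
    return ps.repeated(ps.DrugId.A, 20.0, n_inputs=3, horizon=72.0)


@pytest.fixture(scope="session")
def noiseless_data_A(params_A):
    """Noiseless three-regimen dataset from the reference apoptotic set."""
    return ps.generate_regimen_data(params_A, noise=ps.NoiseModel(sigma=0.0),
                                    seed=3, replicates=1)


@pytest.fixture(scope="session")
def truth_theta_A():
    """Free-parameter values of the reference apoptotic set (topology 3)."""
    return {"alpha_ST0": 0.01, "alpha_TS0": 0.04, "k_d": 0.8,
            "mu_ST": 0.05, "lambda_ST": 0.02, "mu_TS": 0.05,
            "lambda_TS": 0.01, "mu_beta": 0.05, "lambda_beta": 0.02}
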