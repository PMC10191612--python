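"""Shared fixtures: small planted tensors and session-scoped fits.

Everything is generated programmatically and seeded; the session-scoped fit is
shared by the module-calling, association and classification tests to keep the
suite fast.
"""

import numpy as np
import pytest

from microtensor import BayesianTensorFactorization, simulate_case_control, simulate_tensor


@pytest.fixture(scope="session")
def planted():
    """Default-scale planted tensor (clipped, SNR 10) plus its ground truth."""
    tensor, truth = simulate_tensor(seed=11)  # N=60, L=80, K=10, C=6
    return tensor, truth


@pytest.fixture(scope="session")
def planted_fit(planted):
    tensor, _ = planted
    return BayesianTensorFactorization(
        n_modules_max=12, max_iter=250, random_state=0
    ).fit(tensor)


@pytest.fixture(scope="session")
def case_control():
    """Labeled cohort with one shifted module, plus a discovery fit."""
    tensor, labels, truth = simulate_case_control(
        N_case=25, N_control=25, affected_modules=(0,), effect_size=2.0,
        L=40, K=8, seed=21,
    )
    fit = BayesianTensorFactorization(
        n_modules_max=10, max_iter=250, random_state=1
    ).fit(tensor)
    return tensor, labels, truth, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
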