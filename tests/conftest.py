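import numpy as np
import pytest

from thetanet.ncreann import TrainConfig, fit_ncreann
from thetanet.synthetic import LinearVARSpec, gen_linear_var


@pytest.fixture(scope="session")
def fast_train() -> TrainConfig:
    """Reduced training protocol for simulation-heavy tests."""
    return TrainConfig(folds=2, max_epochs=60, patience=10, seed=0)


@pytest.fixture(scope="session")
def var2_data() -> tuple[np.ndarray, np.ndarray]:
    """A 2-channel VAR(1) realisation with a single directed edge 0 -> 1."""
    A = np.zeros((1, 2, 2))
    A[0] = [[0.5, 0.0], [0.4, 0.5]]
    spec = LinearVARSpec(M=2, p_true=1, A=A, n_samples=4000, seed=1)
    series, adj = gen_linear_var(spec)
    return series.data[:, :, 0], adj


@pytest.fixture(scope="session")
def var2_fit(var2_data, fast_train):
    """A fitted network on the shared VAR(1) data (reused across tests)."""
    data, _ = var2_data
    return fit_ncreann(data, 1, fast_train)
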