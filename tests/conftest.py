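import numpy as np
import pytest
from scipy.optimize import linprog

from quantmed.data_model import MediationDataset


def lp_quantile_regression(X, y, tau):
    """Independent exact quantile-regression oracle via the LP formulation.

    min tau*1'u + (1-tau)*1'v  s.t.  X b + u - v = y, u, v >= 0.
    """
    n, k = X.shape
    c = np.concatenate([np.zeros(2 * k), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A, b_eq=y, bounds=[(0, None)] * (2 * k + 2 * n), method="highs")
    assert res.success
    return res.x[:k] - res.x[k : 2 * k]


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture
def toy_dataset(rng):
    """Small dense mediation dataset with two informative mediators."""
    n, p = 120, 8
    x = rng.normal(0, 2, n)
    z = rng.normal(0, 2, (n, 2))
    m = np.outer(x, np.r_[0.9, -0.7, np.zeros(p - 2)]) + 0.3 * z.sum(axis=1)[:, None]
    m += rng.normal(size=(n, p))
    y = 0.5 * x + 1.2 * m[:, 0] - 0.8 * m[:, 1] + 0.5 * z.sum(axis=1) + rng.normal(size=n)
    return MediationDataset(exposure=x, mediators=m, covariates=z, outcome=y)
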