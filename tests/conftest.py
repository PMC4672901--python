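import numpy as np
import pytest

from mbmeta.corpus import table1_fixture
from mbmeta.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def fixture_ds():
    return table1_fixture()


@pytest.fixture(scope="session")
def sim_ds():
    """A mid-sized synthetic corpus with known covariate effects."""
    cfg = SimConfig(seed=11, time_effect=-2.0, benzaldehyde_effect=-5.0)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth


def oracle_meta(estimates, variances):
    """Independent textbook random-effects pooling (plain formulas).

    DerSimonian-Laird tau^2 from Q, then inverse-variance pooling with
    w* = 1/(v + tau^2). Used as the reference path for the package's
    implementation; kept free of any package imports.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    df = y.size - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    ws = 1.0 / (v + tau2)
    pooled = float(np.sum(ws * y) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return {"tau2": tau2, "pooled": pooled, "se": se, "q": q, "i2": i2}


def oracle_mvn_loglik(y, mean, cov):
    """Dense multivariate-normal log-density via scipy (oracle route)."""
    from scipy.stats import multivariate_normal

    return float(multivariate_normal.logpdf(y, mean=mean, cov=cov))
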