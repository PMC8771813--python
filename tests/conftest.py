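import numpy as np
import pytest

import fsadim as fd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_periodic():
    """1000 points uniform on the unit square with torus distances."""
    spec = fd.ManifoldSpec("hypercube", D=2, n=1000, seed=7, boundary="periodic_unit")
    return fd.sample_hypercube(spec)


@pytest.fixture(scope="session")
def wide_model():
    """Wide-range correction model shared by the calibration-dependent tests.

    Calibrated on hard-boundary hypercubes at n = 2500, k = 5 over
    D = 2..80 (every 2nd dimension, 15 realizations each).
    """
    return fd.calibrate(
        n=2500, k=5, d_min=2, d_max=80, n_realizations=15,
        exponents=fd.WIDE_EXPONENTS, method="ols_all", seed=7, d_step=2,
    )
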