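import numpy as np
import pytest

import arci


@pytest.fixture(scope="session")
def benchmark():
    """The fifth-order HRV-like benchmark process (unit innovations, T=1 s)."""
    return arci.benchmark_model()


@pytest.fixture(scope="session")
def benchmark_series(benchmark):
    """One 300-sample realization of the benchmark process."""
    return arci.simulate_linear(benchmark, 300, seed=1234)


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_series):
    return arci.fit_ar(benchmark_series, 5)


@pytest.fixture(scope="session")
def random_stable_models():
    """500 rejection-sampled stable AR models of mixed order (seeded)."""
    rng = np.random.default_rng(20171002)
    models = []
    while len(models) < 500:
        p = int(rng.integers(1, 7))
        coeff = rng.uniform(-1.5, 1.5, size=p)
        if arci.is_stable(coeff):
            models.append(arci.ARModel(coeff, float(rng.uniform(0.1, 5.0))))
    return models
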