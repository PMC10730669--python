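import numpy as np
import pytest

from delaylv import KernelSpec, SpeciesParams, TwoSpeciesModel, load_scenario
from delaylv.kernels import percentile_shift


def random_species(rng, p_max: int = 3, b_max: float = 1.5) -> SpeciesParams:
    """A random valid species (r > m) with the truncation shift at the 99th percentile."""
    r = rng.uniform(0.5, 3.0)
    m = rng.uniform(0.1, 0.8) * r
    mu = rng.uniform(0.05, 0.5)
    a = rng.uniform(0.5, 2.0)
    b = rng.uniform(0.0, b_max)
    p = int(rng.integers(1, p_max + 1))
    ratio = rng.uniform(0.5, 6.0)
    beta = p / ratio
    return SpeciesParams(r, m, mu, a, b, KernelSpec(p, beta, percentile_shift(p, beta, 0.99)))


def random_model(rng, **kw) -> TwoSpeciesModel:
    return TwoSpeciesModel(random_species(rng, **kw), random_species(rng, **kw))


@pytest.fixture(scope="session")
def scenario():
    """Session-cached builtin scenario loader."""
    cache = {}

    def load(name):
        if name not in cache:
            cache[name] = load_scenario(name)
        return cache[name]

    return load


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
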