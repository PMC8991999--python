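import dataclasses

import numpy as np
import pytest

from bwasim.synthpop import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def default_pop():
    """The default calibrated population (n = 3,928 x p = 7,140), shared
    across tests that probe full-scale behaviour."""
    return generate_population(PopulationSpec(seed=0))


@pytest.fixture(scope="session")
def small_pop():
    """A reduced population for fast structural checks."""
    spec = dataclasses.replace(
        PopulationSpec(), n_participants=800, n_features=300, seed=7
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def strong_pop():
    """A dense-signal population where multivariate models have traction
    at small n (higher reliability, stronger loadings, fewer nulls)."""
    spec = dataclasses.replace(
        PopulationSpec(),
        n_participants=1200,
        n_features=250,
        null_fraction=0.4,
        rel_x=0.9,
        brain_share=0.7,
        effect_q99=0.3,
        effect_max=0.5,
        seed=11,
    )
    return generate_population(spec)


def bivariate_population(rho, n, seed):
    """Simple bivariate-normal (feature, phenotype) population."""
    rng = np.random.default_rng([9, seed])
    xy = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return xy[:, [0]], xy[:, 1]
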