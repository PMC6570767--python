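"""Shared fixtures: synthetic datasets with planted structure and fitted maps.

Session-scoped because SOM training at the documented defaults (10×10 grid,
1000 presentations) takes a few seconds and several test modules share it.
"""

import numpy as np
import pytest
from hypothesis import settings

from emtkit import GeneratorConfig, SOMClassifier, generate_expression_profiles

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

PLANT_SEED = 1


@pytest.fixture(scope="session")
def planted_dataset():
    """Default study conditions: 100 genes/class, noise_sd 0.3, seed fixed."""
    return generate_expression_profiles(GeneratorConfig(seed=PLANT_SEED))


@pytest.fixture(scope="session")
def fitted_som(planted_dataset):
    emt = planted_dataset.emt_subset()
    return SOMClassifier(random_state=PLANT_SEED).fit(
        emt.logfc.to_numpy(), emt.annotation.to_numpy()
    )


@pytest.fixture(scope="session")
def zero_noise_dataset():
    cfg = GeneratorConfig(
        n_genes_per_class={"E": 40, "M1": 40, "M2": 40, "M3": 40, "background": 40},
        noise_sd=0.0,
        seed=PLANT_SEED,
    )
    return generate_expression_profiles(cfg)


@pytest.fixture(scope="session")
def zero_noise_som(zero_noise_dataset):
    emt = zero_noise_dataset.emt_subset()
    return SOMClassifier(n_epochs=200, random_state=PLANT_SEED).fit(
        emt.logfc.to_numpy(), emt.annotation.to_numpy()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
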