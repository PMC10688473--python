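import numpy as np
import pytest

from varmode.simulate import SyntheticSpec, gen_structure, gen_variant_dataset
from varmode import structfeat


@pytest.fixture(scope="session")
def separable_dataset():
    """Small, clearly separable labeled dataset (ground truth attached)."""
    spec = SyntheticSpec(
        seed=11, n_genes=60, variants_per_gene=6, class_mix=(0.2, 0.4, 0.4),
        n_informative_features=4, effect_size=2.0, n_noise_features=5,
        missing_rate=0.02,
    )
    variants, features, informative = gen_variant_dataset(spec)
    return variants, features.reset_index(drop=True), informative


@pytest.fixture(scope="session")
def null_dataset():
    """Same shape but zero effect size: features carry no class signal."""
    spec = SyntheticSpec(
        seed=12, n_genes=60, variants_per_gene=6, class_mix=(0.2, 0.4, 0.4),
        n_informative_features=4, effect_size=0.0, n_noise_features=5,
        missing_rate=0.02,
    )
    variants, features, informative = gen_variant_dataset(spec)
    return variants, features.reset_index(drop=True), informative


@pytest.fixture(scope="session")
def chain50():
    return structfeat.parse_pdb(gen_structure(50, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# Small LightGBM configuration used wherever a test needs a trained
# ensemble but not a hyperparameter search.
FAST_CONFIG = {
    "n_members": 3,
    "n_estimators": 40,
    "num_leaves": 15,
    "learning_rate": 0.1,
    "min_child_samples": 5,
}

FAST_SPACE = {
    "learning_rate": ("log", 0.05, 0.2),
    "num_leaves": ("int", 8, 31),
    "min_child_samples": ("int", 5, 20),
    "n_estimators": ("int", 30, 60),
    "n_members": ("int", 5, 7),
}


@pytest.fixture(scope="session")
def fast_config():
    return dict(FAST_CONFIG)


@pytest.fixture(scope="session")
def fast_space():
    return dict(FAST_SPACE)
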