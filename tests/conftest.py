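import numpy as np
import pytest

from dtiscreen.synthetic_fixtures import fixture_ligands, synthetic_dti_dataset


@pytest.fixture(scope="session")
def ligand_table():
    return fixture_ligands()


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable synthetic DTI dataset (entity-pool regime)."""
    return synthetic_dti_dataset(240, 360, effect_size=8.0, seed=101)


@pytest.fixture(scope="session")
def null_dataset():
    """Label-noise-only dataset: features carry no class signal."""
    return synthetic_dti_dataset(240, 360, effect_size=0.0, seed=101)


@pytest.fixture(scope="session")
def small_dataset():
    """Small, moderately separable dataset for fast model tests."""
    return synthetic_dti_dataset(80, 120, effect_size=6.0, seed=7)
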