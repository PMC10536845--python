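import numpy as np
import pytest

from qsarscreen import SyntheticLibrarySpec, gen_bioactivity_library
from qsarscreen.featurize import Mol2VecFeaturizer


@pytest.fixture(scope="session")
def clean_library():
    """A defect-free synthetic library: 200 compounds, modest activity noise."""
    spec = SyntheticLibrarySpec(n_compounds=200, seed=11, noise_sd=0.3)
    return gen_bioactivity_library(spec)


@pytest.fixture(scope="session")
def planted_library():
    """A library with planted duplicates, salts and property outliers and no
    activity noise, for exact closed-loop curation checks."""
    spec = SyntheticLibrarySpec(
        n_compounds=400, seed=7, noise_sd=0.0,
        dup_fraction=0.05, salt_fraction=0.05, outlier_fraction=0.05,
    )
    return gen_bioactivity_library(spec)


@pytest.fixture(scope="session")
def small_featurizer():
    return Mol2VecFeaturizer(dimension=32, seed=3).fit()


@pytest.fixture(scope="session")
def featurized_library(clean_library, small_featurizer):
    """(X, y) for the clean library under the 32-dimensional hashed table."""
    X = small_featurizer.transform(clean_library["smiles"].tolist())
    y = clean_library["gt_pic50"].to_numpy(dtype=float)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
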