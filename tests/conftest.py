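import numpy as np
import pytest

from dceradiomics import generate_case, planted_feature_table


@pytest.fixture(scope="session")
def aligned_case():
    """A phantom with zero planted shifts (series already aligned) and
    ground-truth masks attached — ready for feature extraction."""
    case, truth = generate_case("luminalB", seed=11, max_shift=0)
    return case, truth


@pytest.fixture(scope="session")
def shifted_case():
    """A phantom with nonzero planted inter-series shifts."""
    case, truth = generate_case("HER2", seed=5, max_shift=3)
    return case, truth


@pytest.fixture(scope="session")
def planted_table():
    """60-case feature table where only features {3, 40, 83} carry signal."""
    return planted_feature_table(n_per_class=15, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
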