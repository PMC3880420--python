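import numpy as np
import pytest

from gardensage import SimDesign, default_profiles, generate_count_matrix


@pytest.fixture
def small_design():
    return SimDesign(n_tags=60, seed=11)


@pytest.fixture
def small_matrix(small_design):
    matrix, truth = generate_count_matrix(small_design,
                                          default_profiles(small_design))
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
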