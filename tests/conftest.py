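import numpy as np
import pytest

import functhresh as ft


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study design."""
    return ft.generate_dataset(ft.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def analysis_matrix(default_dataset):
    matrix, _ = ft.build_analysis_matrix(default_dataset.traits)
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
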