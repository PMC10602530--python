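import numpy as np
import pytest

import scrsdx as sx


@pytest.fixture(scope="session")
def axis():
    return sx.canonical_axis()


@pytest.fixture(scope="session")
def small_config():
    return sx.default_config(
        seed=20,
        group_sizes={g: 3 for g in sx.GROUPS},
        cells_per_subject=4,
        acquisitions_per_cell=(3, 5),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sx.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_cells(small_cohort):
    cells, report = sx.run_preprocess(small_cohort.spectra)
    return cells


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
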