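import numpy as np
import pytest

import cephnet as cn
from cephnet import synthetic


@pytest.fixture(scope="session")
def registry():
    return cn.load_registry()


@pytest.fixture(scope="session")
def template():
    return synthetic.default_template()


@pytest.fixture(scope="session")
def landmark_sets(template):
    return synthetic.generate_landmark_sets(template, 200, seed=11)


@pytest.fixture(scope="session")
def landmark_table(registry, landmark_sets):
    return cn.compute_table(landmark_sets, registry)


@pytest.fixture(scope="session")
def preset_table():
    return synthetic.generate_measurement_table(
        synthetic.block_preset(n_subjects=735, seed=1))


@pytest.fixture(scope="session")
def preset_corr(preset_table):
    return cn.pearson_matrix(preset_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_correlation(rng, v: int) -> cn.CorrelationMatrix:
    """Random valid correlation matrix via a Gram matrix of random vectors."""
    x = rng.normal(size=(v + 2, v))
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2, -1, 1)
    np.fill_diagonal(r, 1.0)
    names = [f"V{i:02d}" for i in range(v)]
    return cn.CorrelationMatrix(names, r, n_subjects=v + 2)
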