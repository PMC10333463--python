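import numpy as np
import pytest

from forestcarbon.grids import GridGeometry
from forestcarbon.synthetic import EnsembleConfig, TruthConfig, gen_model_ensemble, gen_truth


@pytest.fixture(scope="session")
def small_truth_cfg():
    return TruthConfig(seed=7, nrows=16, ncols=16, year_start=2000, year_end=2011)


@pytest.fixture(scope="session")
def small_truth(small_truth_cfg):
    return gen_truth(small_truth_cfg)


@pytest.fixture(scope="session")
def small_stack(small_truth):
    cveg, _ = small_truth
    cfg = EnsembleConfig(seed=11, n_models=3, mult_bias=(0.8, 1.0, 1.2),
                         add_bias=(-10.0, 0.0, 10.0), noise_sd=(5.0, 10.0, 15.0))
    return gen_model_ensemble(cveg, cfg)


@pytest.fixture
def geom():
    return GridGeometry(origin_lat=40.0, origin_lon=110.0, cell_size=0.5, nrows=8, ncols=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
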