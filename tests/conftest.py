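import numpy as np
import pytest

from deltaboost import synthetic
from deltaboost.core_data import BrtConfig
from deltaboost.brt import fit_delta


@pytest.fixture(scope="session")
def small_landscape():
    """20x20 lattice with the default 4-variable truth model."""
    grid, truth = synthetic.gen_landscape(n_lon=20, n_lat=20, seed=7)
    return grid, truth


@pytest.fixture(scope="session")
def small_survey(small_landscape):
    grid, truth = small_landscape
    return synthetic.gen_survey(grid, truth, n_stations=300, seed=7)


@pytest.fixture(scope="session")
def fast_config():
    return BrtConfig(
        tc_candidates=[2],
        lr_candidates=[0.05],
        bf_candidates=[0.6],
        cv_folds=4,
        seed=7,
        simplify=False,
    )


@pytest.fixture(scope="session")
def fitted_delta(small_survey, fast_config):
    """One fitted hurdle model shared by diagnostics/prediction tests."""
    return fit_delta(small_survey, "cpue", fast_config)


@pytest.fixture(scope="session")
def prediction_surface(fitted_delta, small_landscape):
    from deltaboost.brt import predict_combined

    grid, _ = small_landscape
    return predict_combined(fitted_delta.model, grid)
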