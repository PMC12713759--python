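import numpy as np
import pytest

from sickstate.classify import CVConfig, nested_cv
from sickstate.simulate import FosSimConfig, default_planted_map, generate_fos


@pytest.fixture(scope="session")
def planted_fos():
    """Well-separated planted data: 48 animals, 40 regions, effect 3 sd."""
    pm = default_planted_map(n_regions=40, regions_per_condition=4, effect=3.0, n_suppressed=1)
    cfg = FosSimConfig(n_animals=48, n_regions=40, planted_map=pm, seed=101)
    table, truth = generate_fos(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_cv_result(planted_fos):
    """A nested-CV run on the separable planted data (5 repetitions)."""
    table, truth = planted_fos
    X = table.drop(columns=["condition", "sex"])
    y = table["condition"].to_numpy()
    cols = sorted(truth.planted_regions())
    cfg = CVConfig(
        n_repetitions=5,
        lambda_grid=(1e-3, 1e-2, 1e-1),
        alpha_grid=(0.3, 0.7),
        seed=202,
    )
    return nested_cv(X[cols], y, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
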