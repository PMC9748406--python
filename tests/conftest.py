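import numpy as np
import pytest

from admixsmc import AdmixtureModel, build_time_grid


@pytest.fixture
def small_grid():
    """8-interval ungrouped grid, t_max = 4."""
    return build_time_grid(8, 4.0)


@pytest.fixture
def small_model(small_grid):
    return AdmixtureModel(
        theta=0.8,
        rho=0.3,
        lambda_a=np.full(small_grid.n_groups, 1.2),
        admix_ratio=0.5,
        t_a_index=3,
        grid=small_grid,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(grid, rng, t_a_index=None, admix_ratio=None):
    """Random valid model on a grid, for property-style checks."""
    return AdmixtureModel(
        theta=float(rng.uniform(0.05, 2.0)),
        rho=float(rng.uniform(0.02, 1.0)),
        lambda_a=rng.uniform(0.2, 4.0, grid.n_groups),
        admix_ratio=float(rng.uniform(0.1, 1.5)) if admix_ratio is None else admix_ratio,
        t_a_index=int(rng.integers(0, grid.n_intervals + 1))
        if t_a_index is None
        else t_a_index,
        grid=grid,
    )
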