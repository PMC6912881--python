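import numpy as np
import pandas as pd
import pytest

from aridrange.grid_core import GridSpec, RasterLayer, RasterStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def unit_grid(n_rows: int, n_cols: int | None = None, cell: float = 1.0) -> GridSpec:
    """Projected grid with unit-ish cells, origin at (0, n_rows*cell)."""
    n_cols = n_cols if n_cols is not None else n_rows
    return GridSpec(
        n_rows=n_rows, n_cols=n_cols,
        x_origin=0.0, y_origin=n_rows * cell,
        cell_size_x=cell, cell_size_y=cell,
    )


@pytest.fixture
def grid3():
    return unit_grid(3)


@pytest.fixture
def small_stack(rng):
    """Three smooth variables on a 10x10 unit grid, one nodata cell."""
    grid = unit_grid(10)
    ii, jj = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
    mask = np.zeros((10, 10), bool)
    mask[7, 7] = True
    layers = [
        RasterLayer("A", grid, np.where(mask, 0, ii * 1.0), mask.copy()),
        RasterLayer("B", grid, np.where(mask, 0, jj * 1.0), mask.copy()),
        RasterLayer("C", grid, np.where(mask, 0, rng.normal(size=(10, 10))), mask.copy()),
    ]
    return RasterStack(layers)


@pytest.fixture
def logit_design(rng):
    """Bernoulli labels from a known 2-variable logistic model, n=800."""
    n = 800
    X = pd.DataFrame({"u": rng.normal(size=n), "v": rng.normal(size=n)})
    eta = -0.5 + 1.8 * X["u"] - 1.2 * X["v"]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return X, y
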