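import numpy as np
import pandas as pd
import pytest

from plotcarbon.core_data import PlotGrid
from plotcarbon.synthetic_plot import SyntheticConfig


@pytest.fixture
def grid_400x500() -> PlotGrid:
    return PlotGrid(400.0, 500.0, 20.0)


@pytest.fixture
def small_grid() -> PlotGrid:
    """5 x 5 quadrats of 20 m."""
    return PlotGrid(100.0, 100.0, 20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_traits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["A", "B", "C"],
            "la": [20.0, 60.0, 40.0],
            "sla": [100.0, 180.0, 140.0],
            "ldmc": [0.45, 0.30, 0.38],
            "wd": [0.70, 0.45, 0.55],
            "max_dbh": [50.0, 20.0, 35.0],
        }
    )


@pytest.fixture
def tiny_stems() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stem_id": [f"s{i}" for i in range(6)],
            "x": [1.0, 5.0, 25.0, 25.0, 45.0, 99.0],
            "y": [1.0, 5.0, 5.0, 6.0, 45.0, 99.0],
            "species_id": ["A", "A", "B", "B", "C", "A"],
            "dbh": [10.0, 5.0, 2.0, 3.0, 8.0, 1.0],
        }
    )


def random_community(rng, n_quadrats=4, n_species=8, max_count=9):
    species = [f"sp{j}" for j in range(n_species)]
    mat = rng.integers(0, max_count + 1, size=(n_quadrats, n_species))
    mat[mat.sum(axis=1) == 0, 0] = 1  # no empty quadrats
    return pd.DataFrame(
        mat, index=pd.Index(range(n_quadrats), name="quadrat_id"), columns=species
    )


def random_traits(rng, n_species=8):
    species = [f"sp{j}" for j in range(n_species)]
    return pd.DataFrame(
        {
            "species_id": species,
            "la": rng.uniform(5, 120, n_species),
            "sla": rng.uniform(60, 250, n_species),
            "ldmc": rng.uniform(0.2, 0.6, n_species),
            "wd": rng.uniform(0.3, 0.9, n_species),
            "max_dbh": rng.uniform(5, 80, n_species),
        }
    )


def small_synth_config(seed=0, **overrides) -> SyntheticConfig:
    """A fast 100 x 100 m configuration for generator tests."""
    defaults = dict(
        plot_width=100.0,
        plot_height=100.0,
        n_species=12,
        n_hills=2,
        hill_height=30.0,
        hill_width=40.0,
        terrain_noise_amp=3.0,
        terrain_noise_kernels=10,
        fertility_kernels=8,
        fertility_range=40.0,
        alt_min=100.0,
        alt_max=150.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)
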