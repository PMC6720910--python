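from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from noiselag import (
    DesignSpec,
    LatticeSpec,
    SimulationConfig,
    add_lags,
    aggregate_counts,
    build_design,
    fit_design,
    generate_covariates,
    make_lattice,
    neighbor_orders,
    simulate_calls,
    trim_for_lags,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_lattice():
    """20-unit rook grid in 4 contiguous districts."""
    return make_lattice(LatticeSpec(n_rows=4, n_cols=5, n_districts=4), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_lattice):
    """A simulated year-long call history on the small lattice.

    380 days so that every weekday, month and period level occurs and the
    design matrix is full rank.
    """
    cfg = SimulationConfig(n_days=380, seed=11)
    rng = np.random.default_rng(11)
    covariates = generate_covariates(small_lattice, cfg.years, rng)
    sim = simulate_calls(cfg, small_lattice, covariates, rng=rng)
    grid = aggregate_counts(sim.events, small_lattice, cfg.start_date, cfg.n_days)
    panel_df = add_lags(grid, neighbor_orders(small_lattice))
    trimmed = trim_for_lags(panel_df)
    return SimpleNamespace(
        lattice=small_lattice,
        config=cfg,
        covariates=covariates,
        sim=sim,
        grid=grid,
        panel=panel_df,
        trimmed=trimmed,
    )


@pytest.fixture(scope="session")
def small_design(small_dataset):
    return build_design(small_dataset.trimmed, small_dataset.covariates, DesignSpec())


@pytest.fixture(scope="session")
def small_fit(small_design):
    return fit_design(small_design)
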