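import numpy as np
import pytest

from mpaconnect import (
    ExperimentConfig,
    GriddedOceanField,
    GridSpec,
    TransportConfig,
    default_registry,
    run_experiment,
)
from mpaconnect.scenarios import demo_grid, future_warming_demo


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def small_grid():
    """10°×10° box with power-of-two-friendly 0.5° spacing and 6 h steps."""
    return GridSpec(
        lon_min=-8.0, lon_max=2.0, lat_min=-4.0, lat_max=6.0,
        n_lon=21, n_lat=21, time_step=6.0, n_times=17,
    )


def make_uniform_field(grid, u=0.0, v=0.0, temp=27.0, land_mask=None):
    shape = grid.shape
    uu = np.full(shape, float(u))
    vv = np.full(shape, float(v))
    tt = np.full(shape, float(temp))
    if land_mask is not None:
        uu[:, :, land_mask] = np.nan
        vv[:, :, land_mask] = np.nan
    return GriddedOceanField(grid=grid, u=uu, v=vv, temperature=tt, land_mask=land_mask)


@pytest.fixture
def uniform_field_factory():
    return make_uniform_field


def warming_experiment_config(
    years=tuple(range(1, 9)),
    total_release=1200,
    pld_days=12.0,
    resolution_deg=1.0,
    master_seed=7,
):
    """Reduced-size future-warming experiment over the nine-site network.

    Same structure as the full study conditions (both seasons, both
    tolerance windows, +3/+4 °C offsets, year-replicates through seeded
    field variability) at a problem size suited to a test run.
    """
    grid = demo_grid(resolution_deg=resolution_deg, time_step_h=6.0,
                     duration_h=pld_days * 24.0 + 6.0)
    return ExperimentConfig(
        scenario=future_warming_demo(seed=0),
        grid=grid,
        registry=default_registry(),
        years=tuple(years),
        seasons=("summer", "winter"),
        windows=("non_acclimated", "acclimated"),
        total_release=total_release,
        events_per_season=1,
        transport=TransportConfig(pld_days=pld_days, log_every_h=24.0),
        master_seed=master_seed,
    )


@pytest.fixture(scope="session")
def warming_bundle():
    """One shared reduced-size warming experiment (8 year-replicates)."""
    return run_experiment(warming_experiment_config())
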