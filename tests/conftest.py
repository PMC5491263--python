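import pytest

from prfclust import (
    FieldSpec,
    GridSpec,
    make_cluster_sheet,
    simulate_timeseries,
)
from prfclust.pipeline import RunConfig, build_run_apertures


@pytest.fixture(scope="session")
def field():
    return FieldSpec()


@pytest.fixture(scope="session")
def run_apertures():
    """One run-level aperture sequence per bar width (all four sweep
    directions concatenated), at the study defaults."""
    return build_run_apertures(RunConfig())


@pytest.fixture(scope="session")
def default_grid():
    return RunConfig().grid_spec()


@pytest.fixture(scope="session")
def reduced_grid():
    """Small grid for brute-force comparisons."""
    return GridSpec.default(
        n_angles=4,
        n_ecc=4,
        ecc_range=(1.0, 8.0),
        n_sigma=3,
        sigma_range=(0.5, 4.0),
        exponents=(0.25, 0.5, 1.0),
    )


@pytest.fixture(scope="session")
def snapped_layout(default_grid):
    """Small two-cluster sheet with on-grid ground truth (120 sites)."""
    return make_cluster_sheet(
        rows_per_map=6,
        n_ecc_cols=5,
        exponent_by_map=(0.25, 0.5, 0.75, 1.0),
        snap_to_grid=default_grid,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(snapped_layout, run_apertures):
    return simulate_timeseries(snapped_layout, run_apertures, noise_sd=0.0, seed=1)
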