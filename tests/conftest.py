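import numpy as np
import pytest

import wastingmap as wm


@pytest.fixture(scope="session")
def region():
    return wm.make_study_region(150.0, 150.0, 10.0)


@pytest.fixture(scope="session")
def covariates(region):
    return wm.simulate_covariate_surfaces(region, seed=101)


@pytest.fixture(scope="session")
def cluster_data(region, covariates):
    """Moderate synthetic survey: 120 clusters over 2 years x 4 seasons."""
    locs = wm.sample_cluster_locations(region, 120, seed=7)
    params = wm.TrueParameters(
        beta={"rainfall": -0.3, "evi": 0.0, "temperature": 0.3,
              "dist_water": 0.0, "urban": 0.0},
        spatial_range=60.0,
        spatial_sd=0.25,
        cluster_sd=0.2,
    )
    return wm.simulate_wasting_data(
        region, locs, covariates, params,
        years=(2007, 2008), n_per_cluster=(40, 80), seed=13,
    )


@pytest.fixture(scope="session")
def small_mesh():
    pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
    return wm.build_mesh(pts, max_edge_km=25.0, buffer_km=25.0)
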