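import numpy as np
import pandas as pd
import pytest

from jellybloom import mesh_spde as ms
from jellybloom import synthetic_data as sd

#: strong-signal coefficients for parameter-recovery harnesses: each slope
#: is large relative to its achievable posterior SD at ~2000 observations
STRONG_SLOPES = {
    "dist_canyon": -0.008,
    "sst": -0.12,
    "pp": -0.003,
    "chl": -1.2,
    "u_cur": 0.05,
    "v_cur": 0.06,
    "month": -0.2,
    "year": 0.0,
}


def strong_truth(sigma_w2=0.05, a=0.3, range_km=50.0):
    """Generative truth with strong regression signal and a mild latent field."""
    return sd.TrueParams(
        beta={"intercept": 0.0, **STRONG_SLOPES},
        kappa=float(np.sqrt(8.0) / range_km),
        sigma_w2=sigma_w2,
        a=a,
        sigma_t2=0.0,
    )


@pytest.fixture(scope="session")
def small_sites():
    return sd.generate_sites(n_sites=20, seed=101)


@pytest.fixture(scope="session")
def small_env(small_sites):
    return sd.generate_environment(
        small_sites, [2007, 2008, 2009, 2010], seed=102
    )


@pytest.fixture(scope="session")
def small_mesh(small_sites):
    mesh = ms.build_mesh(
        small_sites, max_edge_interior=60.0, max_edge_outer=180.0,
        buffer_width=120.0,
    )
    return mesh


@pytest.fixture(scope="session")
def small_projector(small_mesh, small_sites):
    return ms.build_projector(small_mesh, small_sites)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study with strong signal, reused across tests."""
    return sd.simulate_study(
        truth=strong_truth(),
        n_sites=50,
        env_years=range(2007, 2011),
        sampling_years=range(2007, 2011),
        seed=7,
        intercept_target=0.5,
    )
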