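import numpy as np
import pytest

import mortnet as mn


@pytest.fixture(scope="session")
def truth6():
    """A 6-region, 108-month synthetic system with known parameters."""
    return mn.make_truth(n_regions=6, n_months=108, seed=11)


@pytest.fixture(scope="session")
def deaths6(truth6):
    """Poisson mortality panel generated from truth6's forward model."""
    return mn.generate_mortality_panel(truth6, 11)


@pytest.fixture(scope="session")
def dist6(truth6):
    return mn.distance_matrix(truth6.regions)


@pytest.fixture(scope="session")
def total_flux6(truth6, dist6):
    episodic = mn.episodic_flux(
        truth6.regions, dist6,
        truth6.true_model.kappa_e, truth6.true_model.d0_e,
    )
    return mn.total_flux(truth6.commuter_flux, episodic)


def random_flux(regions, rng, max_outflow=0.3):
    """A random valid flux matrix with bounded outflow fractions."""
    n = regions.n
    values = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(values, 0.0)
    frac = rng.uniform(0.01, max_outflow, size=n)
    col = values.sum(axis=0)
    values = values / np.where(col > 0, col, 1.0) * frac * regions.populations
    np.fill_diagonal(values, 0.0)
    return mn.FluxMatrix(region_ids=list(regions.region_ids), values=values,
                         kind="total")
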