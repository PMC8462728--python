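import numpy as np
import pytest

import purefrag as pf


@pytest.fixture(scope="session")
def exp_u0():
    return lambda x: np.exp(-np.asarray(x, dtype=float))


@pytest.fixture(scope="session")
def uniform_kernel():
    return pf.make_kernel("uniform")


@pytest.fixture(scope="session")
def gaussian_kernel():
    return pf.make_kernel("gaussian")


@pytest.fixture(scope="session")
def medium_grid():
    """x in [1e-4, 50], spec-default node density."""
    return pf.LogGrid.from_bounds(1e-4, 50.0, 600)


@pytest.fixture(scope="session")
def small_grid():
    return pf.LogGrid.from_bounds(1e-3, 20.0, 300)


@pytest.fixture(scope="session")
def exp_profile():
    """Exact exponential steady profile on a fine log grid (gamma = 1,
    uniform kernel): the analytic anchor for the Mellin machinery."""
    x = np.geomspace(1e-5, 60.0, 4000)
    g = np.exp(-x)
    g /= np.trapezoid(g, x)
    return pf.SteadyProfile(x=x, g=g, t_source=40.0, gamma=1.0)


@pytest.fixture(scope="session")
def fig6_noiseless(medium_grid):
    """The worked-example configuration: gamma = 1.3, alpha = 1, two-peaked
    Gaussian kernel, exponential initial condition, noiseless densities at
    t = 5, 10, 20, 30, 40."""
    params = pf.FragmentationParameters(gamma=1.3, alpha=1.0)
    kern = pf.make_kernel("two_peaked_gaussian")
    return pf.simulate_experiment(
        params, kern, "exponential", times=[5, 10, 20, 30, 40], n=0, grid=medium_grid
    )


@pytest.fixture(scope="session")
def fig6_result(fig6_noiseless):
    return pf.analyze_experiment(fig6_noiseless)
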