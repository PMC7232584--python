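import numpy as np
import pytest

from hysteresim import (
    FitOptions,
    build_regimen,
    frame_grid,
    severity_presets,
    simulate_plasma,
)


@pytest.fixture(scope="session")
def regimen():
    return build_regimen(70.0, 65.0)


@pytest.fixture(scope="session")
def mean_plasma(regimen):
    return simulate_plasma(regimen, "mean")


@pytest.fixture(scope="session")
def presets():
    return severity_presets()


@pytest.fixture(scope="session")
def frames(mean_plasma):
    return frame_grid(mean_plasma.times[0], mean_plasma.times[-1])


@pytest.fixture(scope="session")
def fast_fit_options():
    """Reduced-budget fit settings for unit tests (not for accuracy checks)."""
    return FitOptions(de_popsize=8, de_maxiter=15, mcmc_steps=120, mcmc_burn=40)


def random_plasma_curve(rng: np.random.Generator, t_max: float = 180.0):
    """Random piecewise-linear plasma curve on [0, t_max], conc U[0, 3500]."""
    from hysteresim import PlasmaCurve

    n_knots = int(rng.integers(3, 12))
    times = np.sort(rng.uniform(0.0, t_max, n_knots))
    times[0], times[-1] = 0.0, t_max
    times = np.unique(times)
    concs = rng.uniform(0.0, 3500.0, times.size)
    return PlasmaCurve(times, concs)
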