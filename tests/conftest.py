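import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import serdslab as sl

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return sl.canonical_grid()


@pytest.fixture(scope="session")
def lipid_pure(grid):
    return sl.synth_pure_spectrum(sl.lipid_like_fixture(), grid)


@pytest.fixture(scope="session")
def protein_pure(grid):
    return sl.synth_pure_spectrum(sl.protein_like_fixture(), grid)


@pytest.fixture(scope="session")
def sim_report():
    return sl.run_simulation_study(sl.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def exp_report():
    return sl.run_experiment_study(sl.ExperimentConfig(n_points=40, seed=2))


@pytest.fixture(scope="session")
def four_pure(grid):
    return [sl.synth_pure_spectrum(sl.fixture_by_label(lb), grid)
            for lb in ("collagen", "protein", "lipid", "bone")]


def gaussian_spectrum(center=1450.0, fwhm=30.0, amplitude=100.0,
                      lo=400.0, hi=3200.0, step=2.0, baseline=None):
    """Single analytic Gaussian band, optionally on a given baseline callable."""
    axis = np.arange(lo, hi + step / 2, step)
    y = amplitude * np.exp(-4 * np.log(2) * (axis - center) ** 2 / fwhm**2)
    if baseline is not None:
        y = y + baseline(axis)
    return sl.Spectrum(axis=axis, intensity=y)
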