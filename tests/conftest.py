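"""Shared fixtures: toy configurations and the simulation samples that
several test modules (and the acceptance tests) reuse.

The expensive simulated fits are session-scoped; their sizes and noise
levels are the study conditions of the claims under test (n = 1000 at
sd 0.15 of the cell spacing for the 5x5 grid, n = 1000 at sd 0.05 for
the six-landmark toy, n = 500 in 3D), not tuning knobs.
"""

import numpy as np
import pytest

import morphoscale as ms


@pytest.fixture(scope="session")
def quincunx():
    return ms.toy_configuration("quincunx")


@pytest.fixture(scope="session")
def grid5():
    return ms.toy_configuration("grid5")


@pytest.fixture(scope="session")
def prologue6():
    return ms.toy_configuration("prologue6")


@pytest.fixture(scope="session")
def giza():
    return ms.toy_configuration("giza")


@pytest.fixture(scope="session")
def grid5_fit(grid5):
    """GPA of the isotropic simulation on the 5x5 grid (sd 0.15, n 1000)."""
    sample = ms.isotropic_sample(ms.SimulationSpec(grid5, 0.15, 1000, seed=1))
    return ms.gpa(sample)


@pytest.fixture(scope="session")
def grid5_spectrum(grid5_fit):
    return ms.principal_warps(mean=ms.Configuration(grid5_fit.mean))


@pytest.fixture(scope="session")
def grid5_scores(grid5_fit, grid5_spectrum):
    return ms.partial_warp_scores(grid5_fit, grid5_spectrum)


@pytest.fixture(scope="session")
def grid5_deflated(grid5_fit, grid5_spectrum):
    return ms.deflate(grid5_fit, grid5_spectrum)


@pytest.fixture(scope="session")
def prologue6_fit(prologue6):
    sample = ms.isotropic_sample(ms.SimulationSpec(prologue6, 0.05, 1000, seed=2))
    return ms.gpa(sample)


@pytest.fixture(scope="session")
def prologue6_deflated(prologue6_fit):
    return ms.deflate(prologue6_fit)


@pytest.fixture(scope="session")
def giza_fit(giza):
    sample = ms.isotropic_sample(ms.SimulationSpec(giza, 0.05, 500, seed=3))
    return ms.gpa(sample)


@pytest.fixture(scope="session")
def giza_deflated(giza_fit):
    return ms.deflate(giza_fit)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
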