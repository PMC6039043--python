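"""Shared fixtures.

The expensive FDTD runs (full-resolution Fresnel validation, the three-arm
nerve experiment, the slab and glass-rod experiments) are session-scoped so
unit, property and acceptance tests reuse a single run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from octfdtd.experiment import fresnel_validation, run_experiment
from octfdtd.fixtures import make_fixture
from octfdtd.source import coherence_length
from octfdtd.spectra import source_spectral_sigma

# fixture-scale study conditions used throughout the suite
NERVE_SCALE = 2.0  # 50 cells per wavelength
SLAB_SCALE = 2.0
GLASS_SCALE = 2.0
SEED = 1


@pytest.fixture(scope="session")
def sigma_25fs():
    fit, _ = source_spectral_sigma(25e-15)
    return fit


@pytest.fixture(scope="session")
def sigma_150fs():
    fit, _ = source_spectral_sigma(150e-15)
    return fit


@pytest.fixture(scope="session")
def lc_25fs(sigma_25fs):
    """Round-trip coherence length of the broadband (25 fs) source."""
    return coherence_length(850e-9, sigma_25fs.sigma)


@pytest.fixture(scope="session")
def fresnel_result():
    """Water-glass interface transmission at the canonical 100 cells/lambda."""
    return fresnel_validation(make_fixture("fresnel", scale=1.0, seed=SEED))


@pytest.fixture(scope="session")
def nerve_result():
    """Three-arm nerve experiment (reference, inactive, active) at fixture scale."""
    return run_experiment(make_fixture("nerve_small", scale=NERVE_SCALE, seed=SEED))


@pytest.fixture(scope="session")
def nerve_zero_delta_result():
    """Nerve experiment whose active arm carries no index perturbation."""
    cfg = make_fixture("nerve_small", scale=2.5, seed=SEED)
    cfg.phantom.active_delta_n = 0.0
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def slab_result():
    """Two-interface glass slab in water, for peak-localisation checks."""
    return run_experiment(make_fixture("slab", scale=SLAB_SCALE, seed=SEED))


@pytest.fixture(scope="session")
def glass_rod_result():
    """Glass rod filled with 0.1 degree-Brix solution, variant arm pure water."""
    return run_experiment(make_fixture("glass_rod_small", scale=GLASS_SCALE, seed=SEED))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
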