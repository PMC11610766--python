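"""Shared fixtures: spectra library, small Monte Carlo runs reused across tests."""
from __future__ import annotations

import numpy as np
import pytest

from cortexmc import pipeline
from cortexmc.fixtures import build_activation_fixture, grey_slab
from cortexmc.spectra import (default_tissue_optics, load_extinction_library,
                              load_tissue_compositions)
from cortexmc.transport import SimulationConfig, run_white_mc


@pytest.fixture(scope="session")
def lib():
    return load_extinction_library()


@pytest.fixture(scope="session")
def compositions():
    return load_tissue_compositions()


@pytest.fixture(scope="session")
def slab_batch_500():
    """White-MC batch on a homogeneous grey slab at 500 nm (small run)."""
    vol = grey_slab((32, 32, 40), 0.25)
    cfg = SimulationConfig(n_photons=8000, wavelengths=np.array([500.0]), seed=42)
    return vol, run_white_mc(vol, default_tissue_optics(), cfg)[500.0]


@pytest.fixture(scope="session")
def activation_sim():
    """Partial (50%) activation slab simulated over the full spectral range."""
    vol, act = build_activation_fixture((40, 40, 36), activated_fraction=0.5,
                                        pitch_mm=0.25)
    return pipeline.simulate_activation_context(
        vol, act, n_photons=15000, seed=7, pool_margin_mm=1.0)


@pytest.fixture(scope="session")
def uniform_sim_small_dc():
    """Whole-volume activation with a 1000x reduced concentration step.

    In this partial-volume-free, linearized limit the modified Beer-Lambert
    inversion recovers the ground truth almost exactly.
    """
    from cortexmc.quantify import DEFAULT_ACTIVATION_DC_UM
    dc = {k: v * 0.001 for k, v in DEFAULT_ACTIVATION_DC_UM.items()}
    vol, act = build_activation_fixture((32, 32, 36), activated_fraction=1.0,
                                        pitch_mm=0.25, dc_uM=dc)
    return pipeline.simulate_activation_context(
        vol, act, n_photons=8000, seed=13, pool_margin_mm=0.0,
        wavelengths=np.arange(440.0, 901.0, 20.0))
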