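"""End-to-end recipes composing the simulator stages.

These helpers wire volume -> white transport -> reweighting -> pooled
rest/activity spectra -> quantification context, which is the input of the
wavelength-selection stage.  They exist so the command line, the test
suite and the reproduction scripts run the exact same chain.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fixtures import activated_surface_mask, build_activation_fixture
from .optimize import QuantificationContext
from .quantify import ActivationModel, activated_composition
from .reconstruct import SensorGeometry, build_cube, pooled_spectra
from .spectra import (ExtinctionLibrary, TissueComposition,
                      default_tissue_optics, load_extinction_library,
                      load_tissue_compositions)
from .transport import PhotonBatch, SimulationConfig, run_white_mc
from .volume import LabelVolume

__all__ = [
    "surface_geometry",
    "rest_activity_compositions",
    "simulate_activation_context",
]


def surface_geometry(vol: LabelVolume, bin_factor: int = 1) -> SensorGeometry:
    """Surface sensor covering the top face of ``vol`` at ``bin_factor`` x pitch."""
    rows, cols = vol.labels.shape[:2]
    pitch = vol.pitch_mm * bin_factor
    return SensorGeometry(shape=(rows // bin_factor, cols // bin_factor),
                          pitch_mm=pitch)


def rest_activity_compositions(act: ActivationModel,
                               lib_comps: Mapping[str, TissueComposition] | None = None,
                               ) -> tuple[dict, dict]:
    """Composition maps for the rest and activity states of the Fig-5-style
    two-region grey-matter model."""
    comps = dict(lib_comps) if lib_comps else load_tissue_compositions()
    grey = comps["grey_matter"]
    rest = {"grey_matter": grey, "activated_grey": grey}
    activity = {"grey_matter": grey,
                "activated_grey": activated_composition(grey, act)}
    return rest, activity


@dataclass
class ActivationSimulation:
    """Everything the quantification/optimization stages need."""

    context: QuantificationContext
    batches: Mapping[float, PhotonBatch]
    volume: LabelVolume
    mask: np.ndarray


def simulate_activation_context(
        vol: LabelVolume | None = None,
        activation: ActivationModel | None = None,
        n_photons: int = 20_000,
        wavelengths: np.ndarray | None = None,
        seed: int = 0,
        bin_factor: int = 1,
        lib: ExtinctionLibrary | None = None,
        pool_margin_mm: float = 1.0) -> ActivationSimulation:
    """Simulate the activated-slab experiment and pool its spectra.

    Runs white Monte Carlo on the two-region activation slab, reweights the
    same photon records with the rest and activity chemistries, pools phi
    and L over the central activated surface (a ``pool_margin_mm`` margin
    keeps the pooled pixels away from the partial-volume edge) and
    interpolates the pooled spectra to the 1-nm grid.
    """
    if vol is None or activation is None:
        v, a = build_activation_fixture()
        vol = vol if vol is not None else v
        activation = activation if activation is not None else a
    lib = lib or load_extinction_library()
    cfg = SimulationConfig(
        n_photons=n_photons,
        wavelengths=(wavelengths if wavelengths is not None
                     else np.arange(400.0, 1001.0, 10.0)),
        seed=seed)
    optics = default_tissue_optics()
    batches = run_white_mc(vol, optics, cfg)

    geom = surface_geometry(vol, bin_factor)
    rest_c, act_c = rest_activity_compositions(activation)
    cube_rest = build_cube(batches, rest_c, lib, geom)
    cube_act = build_cube(batches, act_c, lib, geom)

    mask_full = activated_surface_mask(vol, margin_mm=pool_margin_mm)
    # downsample the mask to the binned grid (block majority)
    if bin_factor > 1:
        rows, cols = geom.shape
        mask = mask_full[:rows * bin_factor, :cols * bin_factor]
        mask = mask.reshape(rows, bin_factor, cols, bin_factor).mean(axis=(1, 3)) > 0.5
    else:
        mask = mask_full

    phi_rest, L_rest = pooled_spectra(cube_rest, mask)
    phi_act, _ = pooled_spectra(cube_act, mask)
    coarse = cube_rest.wavelengths
    grid = np.arange(coarse.min(), coarse.max() + 0.5, 1.0)
    context = QuantificationContext(
        wavelengths=grid,
        phi_rest=np.interp(grid, coarse, phi_rest),
        phi_activity=np.interp(grid, coarse, phi_act),
        pathlength_mm=np.interp(grid, coarse, L_rest),
        lib=lib,
        activation=activation)
    return ActivationSimulation(context=context, batches=batches,
                                volume=vol, mask=mask)
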