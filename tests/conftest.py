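"""Shared fixtures: grid-convolution oracle and cached phantom renders."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from petquant.phantom import nema_iq_spec, render_phantom
from petquant.rc_model import PsfModel, SphereGeom


def grid_convolved_profile(geom: SphereGeom, psf: PsfModel, voxel: float = 0.25):
    """Brute-force 3-D grid convolution of a (walled) sphere with the Gaussian PSF.

    Independent numerical oracle for the closed-form model: antialiased
    voxelization of the geometry on a fine grid, separable Gaussian filtering,
    then the radial profile read along the +x axis through the center.
    Returns (radii_mm, values).
    """
    half = geom.outer_radius_mm + 5.0 * psf.sigma_mm
    n = int(np.ceil(half / voxel))
    ax = np.arange(-n, n + 1) * voxel
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    d = np.sqrt(X**2 + Y**2 + Z**2)
    occ_out = np.clip((geom.outer_radius_mm - d) / voxel + 0.5, 0.0, 1.0)
    occ_in = np.clip((geom.inner_radius_mm - d) / voxel + 0.5, 0.0, 1.0)
    img = geom.background_level * (1.0 - occ_out) + geom.sphere_level * occ_in
    img = gaussian_filter(img, sigma=psf.sigma_mm / voxel, mode="nearest")
    return ax[n:], img[n:, n, n]


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_convolved_profile


@pytest.fixture(scope="session")
def default_psf():
    return PsfModel(fwhm_mm=6.5)


@pytest.fixture(scope="session")
def nema_image():
    """Noiseless default-resolution (2 mm voxel) phantom render."""
    return render_phantom(nema_iq_spec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def nema_fine_image():
    """Noiseless 1 mm voxel phantom render for model-agreement oracles."""
    spec = nema_iq_spec(shape=(400, 400, 240), voxel_mm=1.0, noise_sd=0.0, seed=0)
    return render_phantom(spec)
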