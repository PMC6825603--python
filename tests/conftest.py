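"""Shared fixtures: small, session-cached focal fields and volumes.

Focal-field propagation is the expensive step, so the PSFs used by many
tests are computed once per session at reduced (but sufficient) grid
sizes.
"""

import numpy as np
import pytest

from aostedfcs import optics as O
from aostedfcs.volume import effective_volume


@pytest.fixture(scope="session")
def sted_cfg():
    return O.OpticalConfig()


@pytest.fixture(scope="session")
def grid64():
    return O.PupilGrid(64)


@pytest.fixture(scope="session")
def roi_small():
    return O.FocalROI((1000.0, 1000.0, 2000.0), (20.0, 20.0, 40.0))


@pytest.fixture(scope="session")
def zsted_psf(sted_cfg, grid64, roi_small):
    return O.focal_intensity(O.zsted_mask(grid64), sted_cfg, roi_small)


@pytest.fixture(scope="session")
def confocal_psf(grid64, roi_small):
    """Combined excitation x detection profile on the same grid."""
    flat = O.PhaseMap(np.zeros((64, 64)), grid64.mask)
    exc = O.focal_intensity(flat, O.OpticalConfig(wavelength=640.0), roi_small)
    det = O.focal_intensity(flat, O.OpticalConfig(wavelength=685.0), roi_small)
    return O.PSF3D(exc.intensity * det.intensity, roi_small.voxel, exc.axes)


@pytest.fixture(scope="session")
def confocal_volume(confocal_psf):
    return effective_volume(confocal_psf, None, 0.0)
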