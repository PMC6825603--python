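"""Reference computations of the instrument's analytic calibration numbers.

Both quantities are pure optics: no randomness, no data.  They are used
by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from .optics import (AberrationState, FocalROI, OpticalConfig, PupilGrid,
                     compose_pupil, depth_aberration, focal_intensity,
                     pattern_min_shift, zsted_mask)

__all__ = ["tip_null_shift_nm", "depth_primary_spherical_rms"]


def tip_null_shift_nm(amplitude: float = 1.0, pupil_samples: int = 192,
                      extent=(2000.0, 2000.0, 2000.0),
                      voxel=(10.0, 10.0, 20.0)) -> float:
    """Lateral displacement (nm) of the z-STED null per ``amplitude`` rad rms
    of Noll tip, measured by sub-voxel extremum tracking of the focal field
    at 755 nm / NA 1.4 (analytic cross-check: λ/(π·NA) per rad)."""
    cfg = OpticalConfig(pupil_samples=pupil_samples)
    grid = PupilGrid(pupil_samples)
    roi = FocalROI(extent, voxel)
    mask = zsted_mask(grid)
    ref = focal_intensity(mask, cfg, roi)
    pupil = compose_pupil(mask, AberrationState({"tip": amplitude}), cfg, grid)
    aberrated = focal_intensity(pupil, cfg, roi)
    dx, _, _ = pattern_min_shift(aberrated, ref, refine_radius=8)
    return abs(dx)


def depth_primary_spherical_rms(depth_um: float = 3.0,
                                n_immersion: float = 1.518,
                                n_sample: float = 1.398,
                                grid_samples: int = 1024) -> float:
    """Primary-spherical (Noll j=11) rms amplitude of the index-mismatch
    pupil aberration at the given focusing depth (oil immersion into a 1:1
    water:glycerol medium by default), with piston/tip/tilt/defocus removed
    over the transmitted sub-aperture."""
    cfg = OpticalConfig(n_immersion=n_immersion, n_sample=n_sample)
    state = depth_aberration(depth_um, cfg, modes=(11, 22),
                             grid_samples=grid_samples)
    return abs(state.amplitude("noll:11"))
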