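"""Pupil-phase engineering and scalar focal-field computation.

This module generates pupil phase functions (Noll-indexed Zernike modes,
the high-NA defocus phase, the central π-step used to create a z-STED
"bottle beam"), propagates a phased pupil to a 3-D focal intensity grid
with a scalar Debye integral, localizes the depletion-pattern null with
sub-voxel precision, and decomposes the depth-induced refractive-index-
mismatch aberration into Zernike modes.

Conventions
-----------
* Lengths in nm, phases in rad; Zernike amplitudes are rms radians over
  the unit pupil disk (Noll normalization).
* ``tip``/``tilt`` are Noll j=2,3.  The instrument's defocus mode is the
  high-NA defocus phase a·sqrt(1-(NA·ρ/n)²); its amplitude unit is
  calibrated so that one unit displaces the focus axially by 339 nm (the
  tabulated shift at λ=755 nm, NA=1.4, n=1.518).
* A positive mode amplitude adds that phase to the wavefront; a
  "correction" is the additive inverse of the aberration present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial, pi, sqrt

import numpy as np
import tifffile

__all__ = [
    "OpticalConfig",
    "PupilGrid",
    "PhaseMap",
    "AberrationState",
    "FocalROI",
    "PSF3D",
    "noll_to_nm",
    "zernike_phase",
    "high_na_defocus_phase",
    "hnd_amplitude_scale",
    "zsted_mask",
    "focal_intensity",
    "pattern_min_shift",
    "depth_aberration",
    "compose_pupil",
    "psf_to_tiff",
    "psf_from_tiff",
    "phase_to_tiff",
    "TIP_SHIFT_NM_PER_RAD",
    "TILT_SHIFT_NM_PER_RAD",
    "DEFOCUS_SHIFT_NM_PER_RAD",
    "EQUAL_AREA_STEP_RADIUS",
]

#: Tabulated focal shifts per 1 rad rms of the repositioning modes
#: (λ=755 nm, NA=1.4 oil immersion).  Tip/tilt follow λ/(π·NA).
TIP_SHIFT_NM_PER_RAD = 172.0
TILT_SHIFT_NM_PER_RAD = 172.0
DEFOCUS_SHIFT_NM_PER_RAD = 339.0

#: π-step radius that balances the inner and outer pupil areas (bottle beam).
EQUAL_AREA_STEP_RADIUS = 1.0 / sqrt(2.0)


@dataclass(frozen=True)
class OpticalConfig:
    """Physical parameters of one beam path.

    Defaults describe the depletion path: 755 nm through a 100×/1.4 oil
    immersion objective (n=1.518).  ``n_sample`` is the specimen medium
    index used for depth-aberration calculations.
    """

    wavelength: float = 755.0           # nm
    numerical_aperture: float = 1.4
    n_immersion: float = 1.518
    n_sample: float = 1.518
    pupil_samples: int = 128

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.numerical_aperture <= 0:
            raise ValueError("numerical aperture must be positive")
        if self.pupil_samples < 32:
            raise ValueError("pupil_samples must be >= 32")


EXCITATION_CONFIG = OpticalConfig(wavelength=640.0)


class PupilGrid:
    """Square sample grid over the unit pupil disk (cell-centered)."""

    def __init__(self, n: int = 128):
        if n < 32:
            raise ValueError("pupil grid must have >= 32 samples")
        self.n = n
        x = (np.arange(n) + 0.5) / n * 2.0 - 1.0
        self.x = x
        self.X, self.Y = np.meshgrid(x, x, indexing="xy")
        self.rho = np.hypot(self.X, self.Y)
        self.phi = np.arctan2(self.Y, self.X)
        self.mask = self.rho <= 1.0

    def __eq__(self, other):
        return isinstance(other, PupilGrid) and other.n == self.n

    def __hash__(self):
        return hash(("PupilGrid", self.n))


@dataclass
class PhaseMap:
    """Phase (rad) on a pupil grid; zero outside the disk mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals[self.mask])):
            raise ValueError("phase must be finite on the pupil disk")
        vals = np.where(self.mask, vals, 0.0)
        self.values = vals

    def __add__(self, other: "PhaseMap") -> "PhaseMap":
        if self.values.shape != other.values.shape:
            raise ValueError("phase maps must share a grid")
        return PhaseMap(self.values + other.values, self.mask & other.mask)

    def rms(self) -> float:
        v = self.values[self.mask]
        return float(np.sqrt(np.mean(v * v)))


_MODE_ALIASES = {"noll:2": "tip", "noll:3": "tilt"}


def _canonical_mode(mode_id) -> str:
    if isinstance(mode_id, (int, np.integer)):
        mode_id = f"noll:{int(mode_id)}"
    mode_id = str(mode_id)
    mode_id = _MODE_ALIASES.get(mode_id, mode_id)
    if mode_id in ("tip", "tilt", "hnd_defocus"):
        return mode_id
    if mode_id.startswith("noll:"):
        j = int(mode_id.split(":", 1)[1])
        if j < 1:
            raise ValueError(f"invalid Noll index in mode {mode_id!r}")
        return f"noll:{j}"
    raise KeyError(f"unknown aberration mode {mode_id!r}")


@dataclass
class AberrationState:
    """Map mode-id -> amplitude (rad rms); missing key means zero.

    Mode ids: ``tip``, ``tilt``, ``hnd_defocus`` and ``noll:j`` for j >= 4.
    ``noll:2``/``noll:3`` are canonicalized to tip/tilt.
    """

    modes: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for k, v in dict(self.modes).items():
            v = float(v)
            if not np.isfinite(v):
                raise ValueError("mode amplitudes must be finite")
            clean[_canonical_mode(k)] = clean.get(_canonical_mode(k), 0.0) + v
        self.modes = clean

    def amplitude(self, mode_id) -> float:
        return self.modes.get(_canonical_mode(mode_id), 0.0)

    def with_mode(self, mode_id, amplitude: float) -> "AberrationState":
        d = dict(self.modes)
        d[_canonical_mode(mode_id)] = float(amplitude)
        return AberrationState(d)

    def add(self, mode_id, delta: float) -> "AberrationState":
        m = _canonical_mode(mode_id)
        d = dict(self.modes)
        d[m] = d.get(m, 0.0) + float(delta)
        return AberrationState(d)

    def __add__(self, other: "AberrationState") -> "AberrationState":
        d = dict(self.modes)
        for k, v in other.modes.items():
            d[k] = d.get(k, 0.0) + v
        return AberrationState(d)

    def __neg__(self) -> "AberrationState":
        return AberrationState({k: -v for k, v in self.modes.items()})

    def nonzero(self) -> dict:
        return {k: v for k, v in self.modes.items() if v != 0.0}


# ---------------------------------------------------------------------------
# Zernike modes (Noll indexing)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def noll_to_nm(j: int):
    """Return (n, m_signed) for Noll index j (m<0 encodes the sin term)."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    while (n + 1) * (n + 2) // 2 < j:
        n += 1
    jr = j - n * (n + 1) // 2 - 1
    if n % 2 == 0:
        m = 2 * ((jr + 1) // 2)
    else:
        m = 2 * (jr // 2) + 1
    if m > 0 and j % 2 == 1:
        m = -m
    return n, m


def _zernike_values(j: int, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    n, m_signed = noll_to_nm(j)
    m = abs(m_signed)
    R = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        R += c * rho ** (n - 2 * k)
    if m == 0:
        return sqrt(n + 1) * R
    ang = np.sin(m * phi) if m_signed < 0 else np.cos(m * phi)
    return sqrt(2 * (n + 1)) * R * ang


def zernike_phase(j: int, grid: PupilGrid) -> PhaseMap:
    """Noll-normalized Zernike mode j on the pupil grid (unit rms amplitude)."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    vals = _zernike_values(j, grid.rho, grid.phi)
    return PhaseMap(np.where(grid.mask, vals, 0.0), grid.mask)


def hnd_amplitude_scale(cfg: OpticalConfig) -> float:
    """Phase prefactor that makes one high-NA-defocus unit shift the focus
    axially by ``DEFOCUS_SHIFT_NM_PER_RAD`` nm.

    A pupil phase z·(2π/λ)·sqrt(n²−NA²ρ²) refocuses by z, so the unit
    amplitude corresponds to z = 339 nm of refocus.
    """
    return 2.0 * pi * cfg.n_immersion * DEFOCUS_SHIFT_NM_PER_RAD / cfg.wavelength


def high_na_defocus_phase(a: float, cfg: OpticalConfig, grid: PupilGrid,
                          scaled: bool = True) -> PhaseMap:
    """High-NA defocus phase a·sqrt(1−(NA·ρ/n)²) on the pupil.

    With ``scaled=True`` (default) the amplitude ``a`` is in the
    calibrated unit (one unit = 339 nm axial shift); ``scaled=False``
    returns the bare profile a·sqrt(1−(NA·ρ/n)²).
    """
    s = (NA := cfg.numerical_aperture) / cfg.n_immersion
    arg = 1.0 - (s * grid.rho) ** 2
    profile = np.sqrt(np.clip(arg, 0.0, None))
    amp = a * (hnd_amplitude_scale(cfg) if scaled else 1.0)
    return PhaseMap(np.where(grid.mask, amp * profile, 0.0), grid.mask)


def zsted_mask(grid: PupilGrid, step_radius: float = EQUAL_AREA_STEP_RADIUS) -> PhaseMap:
    """Central π phase step creating the z-STED bottle-beam depletion focus."""
    if not 0.0 < step_radius < 1.0:
        raise ValueError("step_radius must lie strictly between 0 and 1")
    vals = np.where(grid.rho < step_radius, pi, 0.0)
    return PhaseMap(np.where(grid.mask, vals, 0.0), grid.mask)


def mode_phase(mode_id, cfg: OpticalConfig, grid: PupilGrid) -> PhaseMap:
    """Unit-amplitude phase of a correction mode."""
    m = _canonical_mode(mode_id)
    if m == "tip":
        return zernike_phase(2, grid)
    if m == "tilt":
        return zernike_phase(3, grid)
    if m == "hnd_defocus":
        return high_na_defocus_phase(1.0, cfg, grid)
    return zernike_phase(int(m.split(":")[1]), grid)


def compose_pupil(base: PhaseMap, state: AberrationState, cfg: OpticalConfig,
                  grid: PupilGrid) -> PhaseMap:
    """Pointwise sum of a base pupil phase and the state's mode phases."""
    total = base.values.copy()
    for mode_id, amp in state.modes.items():
        if amp == 0.0:
            continue
        total = total + amp * mode_phase(mode_id, cfg, grid).values
    return PhaseMap(total, base.mask)


# ---------------------------------------------------------------------------
# Focal field (scalar Debye integral)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalROI:
    """Focal region of interest: full extents and voxel pitches, nm."""

    extent: tuple = (2000.0, 2000.0, 4000.0)   # (x, y, z) full span
    voxel: tuple = (10.0, 10.0, 20.0)          # (dx, dy, dz)

    def axes(self):
        out = []
        for ext, d in zip(self.extent, self.voxel):
            half = int(np.floor(ext / (2.0 * d)))
            out.append(np.arange(-half, half + 1) * d)
        return out  # x, y, z coordinate vectors, each containing 0


@dataclass
class PSF3D:
    """3-D focal intensity on a regular grid, normalized to max = 1.

    ``intensity`` is indexed (z, y, x); ``axes`` are the (x, y, z)
    coordinate vectors in nm relative to the nominal focus.
    """

    intensity: np.ndarray
    voxel: tuple
    axes: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        inten = np.asarray(self.intensity, dtype=float)
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        peak = inten.max()
        if peak > 0:
            inten = inten / peak
        self.intensity = inten


def focal_intensity(pupil_phase: PhaseMap, cfg: OpticalConfig,
                    roi: FocalROI = FocalROI()) -> PSF3D:
    """Propagate a phased, uniformly filled pupil to a 3-D intensity grid.

    Scalar Debye approximation: each pupil sample contributes a plane wave
    with transverse wavevector k0·NA·ρ and axial wavevector
    k0·sqrt(n²−NA²ρ²); components beyond the propagating aperture
    (NA·ρ > n) are discarded.
    """
    grid_n = pupil_phase.values.shape[0]
    grid = PupilGrid(grid_n)
    k0 = 2.0 * pi / cfg.wavelength
    NA, n = cfg.numerical_aperture, cfg.n_immersion

    kz_arg = n * n - (NA * grid.rho) ** 2
    propagating = pupil_phase.mask & (kz_arg > 0)
    kz = np.where(propagating, k0 * np.sqrt(np.clip(kz_arg, 0.0, None)), 0.0)
    P = np.where(propagating, np.exp(1j * pupil_phase.values), 0.0)

    xs, ys, zs = roi.axes()
    kt = k0 * NA * grid.x                       # transverse wavevector samples
    Ex = np.exp(1j * np.outer(xs, kt))          # (nx, np)
    Ey = np.exp(1j * np.outer(kt, ys))          # (np, ny)

    # subtract the mean axial wavevector: pure piston per z-plane, but keeps
    # the complex exponents well-conditioned for large z
    kz0 = kz[propagating].mean()
    inten = np.empty((zs.size, ys.size, xs.size))
    for iz, z in enumerate(zs):
        U = (P * np.exp(1j * (kz - kz0) * z)).T   # axis0 -> pupil x
        E = Ex @ U @ Ey                           # (nx, ny)
        inten[iz] = np.abs(E).T ** 2              # stored (ny, nx)
    # raw focal peak (per unit pupil area) before max-normalization: at fixed
    # laser power an aberrated pattern has a lower peak, which matters when
    # the pattern sets a depletion strength
    meta = {"wavelength": cfg.wavelength, "NA": NA, "n_immersion": n,
            "peak_intensity": float(inten.max()) / grid_n ** 4}
    if roi.voxel[0] > 20.0 or roi.voxel[2] > 40.0:
        meta["coarse_grid"] = True
        warnings.warn("focal ROI voxel may be too coarse to resolve the pattern")
    return PSF3D(inten, roi.voxel, (xs, ys, zs), meta)


def _parabolic_offset(fm, f0, fp):
    denom = fm - 2.0 * f0 + fp
    if denom == 0:
        return 0.0
    return 0.5 * (fm - fp) / denom


def _parabola_vertex(values: np.ndarray, centre: int, r: int) -> float:
    """Vertex offset (voxels) of a least-squares parabola around ``centre``.

    A multi-point window makes the refinement robust to the shallow
    interference ripples at the bottom of the depletion null, where the
    intensity floor is orders of magnitude below the surrounding slope.
    """
    lo = max(centre - r, 0)
    hi = min(centre + r + 1, values.size)
    u = np.arange(lo, hi) - centre
    a, b, _ = np.polyfit(u, values[lo:hi], 2)
    if a == 0:
        return 0.0
    off = -b / (2.0 * a)
    return float(np.clip(off, -r, r))


def _descend(I: np.ndarray, start, track: str):
    """Walk to the nearest local extremum from ``start`` (3³ neighborhoods).

    Ties break to the lower-index voxel via argmin/argmax ordering.
    """
    nz, ny, nx = I.shape
    cur = tuple(start)
    pick = np.argmin if track == "min" else np.argmax
    for _ in range(max(nz, ny, nx)):
        z0, y0, x0 = cur
        zs = slice(max(z0 - 1, 0), min(z0 + 2, nz))
        ys = slice(max(y0 - 1, 0), min(y0 + 2, ny))
        xs = slice(max(x0 - 1, 0), min(x0 + 2, nx))
        block = I[zs, ys, xs]
        dz, dy, dx = np.unravel_index(pick(block), block.shape)
        nxt = (zs.start + dz, ys.start + dy, xs.start + dx)
        if nxt == cur:
            return cur
        cur = nxt
    raise ValueError("no interior extremum found near the start point")


def pattern_min_shift(psf_aberrated: PSF3D, psf_reference: PSF3D,
                      track: str = "auto", refine_radius: int = 5):
    """Sub-voxel displacement (dx, dy, dz) nm of the tracked focal extremum.

    The reference pattern decides what is tracked: the central intensity
    minimum (z-STED null) or maximum (confocal focus).  The extremum is
    found by monotone descent on a lightly smoothed copy starting from
    the nominal focus (so the connected central extremum is followed
    rather than spurious off-axis dark valleys), then refined per axis by
    a least-squares parabola over ±``refine_radius`` voxels.
    """
    if psf_aberrated.intensity.shape != psf_reference.intensity.shape:
        raise ValueError("PSFs must share a grid")
    if psf_aberrated.voxel != psf_reference.voxel:
        raise ValueError("PSFs must share voxel sizes")
    from scipy.ndimage import gaussian_filter

    xs, ys, zs = psf_reference.axes
    shape = psf_reference.intensity.shape       # (nz, ny, nx)
    centre = (shape[0] // 2, shape[1] // 2, shape[2] // 2)

    if track == "auto":
        track = "min" if psf_reference.intensity[centre] < 0.5 else "max"

    def locate(psf, start):
        smooth = gaussian_filter(psf.intensity, sigma=1.0)
        iz, iy, ix = _descend(smooth, start, track)
        r = refine_radius
        if (ix < r or ix >= shape[2] - r or iy < r or iy >= shape[1] - r
                or iz < r or iz >= shape[0] - r):
            raise ValueError("tracked extremum too close to the grid border")
        I = psf.intensity
        dx = _parabola_vertex(I[iz, iy, :], ix, r)
        dy = _parabola_vertex(I[iz, :, ix], iy, r)
        dz = _parabola_vertex(I[:, iy, ix], iz, r)
        return (iz, iy, ix), (xs[ix] + dx * psf.voxel[0],
                              ys[iy] + dy * psf.voxel[1],
                              zs[iz] + dz * psf.voxel[2])

    ref_idx, pr = locate(psf_reference, centre)
    _, pa = locate(psf_aberrated, ref_idx)
    return tuple(a - r for a, r in zip(pa, pr))


# ---------------------------------------------------------------------------
# Depth-induced aberration
# ---------------------------------------------------------------------------

def depth_aberration(depth_um: float, cfg: OpticalConfig,
                     modes=(11, 22), grid_samples: int = 512,
                     defocus: str = "zernike") -> AberrationState:
    """Zernike decomposition of the index-mismatch aberration at a depth.

    The pupil phase for focusing ``depth_um`` µm into a medium of index
    ``cfg.n_sample`` through immersion of index ``cfg.n_immersion`` is

        (2π/λ)·d·(sqrt(n_s²−NA²ρ²) − sqrt(n_i²−NA²ρ²)),

    evaluated on the transmitted sub-aperture ρ ≤ n_s/NA.  Piston, tip,
    tilt and defocus are removed by a joint least-squares fit (``defocus``
    selects the Zernike j=4 mode or the instrument's high-NA defocus
    profile); the requested mode coefficients (rad rms) are returned.
    """
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    NA, ni, ns = cfg.numerical_aperture, cfg.n_immersion, cfg.n_sample
    lam = cfg.wavelength
    d_nm = depth_um * 1e3

    grid = PupilGrid(grid_samples)
    rho_max = min(1.0, ns / NA)
    sub = grid.mask & (grid.rho <= rho_max) & ((NA * grid.rho) < ni)
    r, p = grid.rho[sub], grid.phi[sub]

    phase = (2.0 * pi / lam) * d_nm * (
        np.sqrt(ns * ns - (NA * r) ** 2) - np.sqrt(ni * ni - (NA * r) ** 2)
    )

    if defocus == "zernike":
        defocus_col = _zernike_values(4, r, p)
    elif defocus == "high_na":
        defocus_col = np.sqrt(np.clip(1.0 - (NA * r / ni) ** 2, 0.0, None))
    else:
        raise ValueError("defocus must be 'zernike' or 'high_na'")

    cols = [np.ones_like(r), _zernike_values(2, r, p), _zernike_values(3, r, p),
            defocus_col]
    cols += [_zernike_values(j, r, p) for j in modes]
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, phase, rcond=None)
    return AberrationState({f"noll:{j}": float(c) for j, c in zip(modes, coef[4:])})


# ---------------------------------------------------------------------------
# TIFF import/export
# ---------------------------------------------------------------------------

def psf_to_tiff(psf: PSF3D, path):
    """Write a PSF as a multi-page float32 TIFF (z pages) + JSON sidecar."""
    path = str(path)
    dx, dy, dz = psf.voxel
    tifffile.imwrite(
        path, psf.intensity.astype(np.float32),
        resolution=(1e7 / dx, 1e7 / dy), resolutionunit="CENTIMETER",
    )
    sidecar = {
        "voxel_nm": list(psf.voxel),
        "shape_zyx": list(psf.intensity.shape),
        "meta": {k: v for k, v in psf.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def psf_from_tiff(path) -> PSF3D:
    path = str(path)
    inten = np.asarray(tifffile.imread(path), dtype=float)
    if inten.ndim == 2:
        inten = inten[None]
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    voxel = tuple(sidecar["voxel_nm"])
    nz, ny, nx = inten.shape
    axes = (
        (np.arange(nx) - nx // 2) * voxel[0],
        (np.arange(ny) - ny // 2) * voxel[1],
        (np.arange(nz) - nz // 2) * voxel[2],
    )
    return PSF3D(inten, voxel, axes, sidecar.get("meta", {}))


def phase_to_tiff(phase: PhaseMap, path):
    """Write a pupil phase map as a 32-bit float TIFF (radians)."""
    tifffile.imwrite(str(path), phase.values.astype(np.float32))
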