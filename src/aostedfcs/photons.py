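"""Synthetic photon-count traces from diffusing, blinking emitters.

A fixed number of molecules diffuses (Brownian or fractional-Brownian for
anomalous subdiffusion with exponent α) in a periodic box around the
observation volume.  Each molecule blinks between a bright and a dark
(triplet) state as a two-state Markov process, and detected counts per
time bin are Poisson with rate

    rate(t) = Σ_mol brightness0 · dt · V(r_mol(t)) · bright(t)  +  bg · dt,

where V is the relative detection probability of the effective volume
(grid-interpolated, or an analytic 3-D Gaussian on the fast path).

Everything is reproducible: molecule m always consumes the m-th child of
``SeedSequence(seed)``, so traces are bit-identical for a given
configuration regardless of internal batching.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
from scipy.ndimage import map_coordinates

from .optics import (AberrationState, FocalROI, OpticalConfig, PhaseMap,
                     PSF3D, EXCITATION_CONFIG, compose_pupil, focal_intensity,
                     zsted_mask, PupilGrid)
from .volume import EffectiveVolume, effective_volume

__all__ = [
    "SimConfig",
    "PhotonTrace",
    "simulate_trajectories",
    "triplet_states",
    "photon_trace",
    "simulate_trace",
    "SimulatedMicroscope",
    "fractional_gaussian_noise",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth physical parameters of a simulated measurement.

    Units: nm, s, counts/s.  ``D`` is the Brownian diffusion coefficient
    (nm²/s); for anomalous diffusion set ``alpha`` < 1 and ``gamma``
    (nm²/s^α), giving a per-axis MSD of 2·Γ·t^α.  Triplet defaults follow
    the solution preset (12 µs dark-state correlation time); the cell
    preset uses 5 µs.
    """

    box: float = 3600.0             # periodic cube edge, nm
    n_molecules: int = 50
    D: float = 5e7                  # nm²/s  (~50 µm²/s, dye in viscous solution)
    alpha: float = 1.0
    gamma: float | None = None      # nm²/s^alpha; defaults to D
    dt: float = 1e-6                # s (1 MHz sampling)
    duration: float = 3.0           # s
    brightness0: float = 150e3      # peak counts/s per molecule
    triplet_T: float = 0.15         # stationary dark fraction
    triplet_tau: float = 12e-6      # s
    background: float = 300.0       # counts/s
    seed: int = 0
    bleach_tau: float | None = None  # optional exponential brightness decay, s

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 100 * self.dt:
            raise ValueError("duration must be at least 100 bins")
        if not 0 <= self.triplet_T < 1:
            raise ValueError("triplet fraction must be in [0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.box <= 0 or self.n_molecules < 0:
            raise ValueError("box must be positive, n_molecules >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def gamma_eff(self) -> float:
        return self.D if self.gamma is None else self.gamma


@dataclass
class PhotonTrace:
    """Counts per uniform time bin.  Raw traces are integer; bleach-corrected
    traces are real-valued (flagged in ``meta``)."""

    counts: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.issubdtype(self.counts.dtype, np.integer) and np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        return self.counts.size * self.dt


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def fractional_gaussian_noise(n: int, alpha: float, rng: np.random.Generator,
                              n_channels: int = 1) -> np.ndarray:
    """Unit-scale fractional Gaussian noise via Davies–Harte embedding.

    Returns increments with covariance
    Cov(X_i, X_{i+k}) = (|k+1|^α − 2|k|^α + |k−1|^α)/2, i.e. the increment
    process of fractional Brownian motion with Hurst H = α/2 and
    Var(B_t) = t^α on the integer grid.
    """
    if alpha == 1.0:
        return rng.standard_normal((n_channels, n))
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha
                   + np.abs(k - 1) ** alpha)
    row = np.concatenate([gamma, gamma[-2:0:-1]])     # circulant row, M = 2n
    M = row.size
    eig = np.fft.fft(row).real
    # eigenvalues are non-negative for H <= 1/2 up to roundoff
    eig = np.clip(eig, 0.0, None)
    half = M // 2
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        v = np.empty(M, dtype=complex)
        v[0] = rng.standard_normal()
        v[half] = rng.standard_normal()
        re = rng.standard_normal(half - 1)
        im = rng.standard_normal(half - 1)
        v[1:half] = (re + 1j * im) / sqrt(2.0)
        v[half + 1:] = np.conj(v[1:half][::-1])
        x = np.fft.fft(np.sqrt(eig / M) * v)
        out[c] = x[:n].real
    return out


def _increments(cfg: SimConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-axis position increments (3, n_steps) for one molecule, nm."""
    if cfg.alpha == 1.0:
        sigma = sqrt(2.0 * cfg.D * cfg.dt)
        return sigma * rng.standard_normal((3, n_steps), dtype=np.float32)
    scale = sqrt(2.0 * cfg.gamma_eff * cfg.dt ** cfg.alpha)
    return scale * fractional_gaussian_noise(n_steps, cfg.alpha, rng, 3)


def _molecule_path(cfg: SimConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    x0 = rng.uniform(-cfg.box / 2.0, cfg.box / 2.0, size=(3, 1))
    pos = np.cumsum(_increments(cfg, n_steps, rng), axis=1)
    pos += x0
    half = cfg.box / 2.0
    pos += half
    pos %= cfg.box
    pos -= half
    return pos


def simulate_trajectories(cfg: SimConfig, n_steps: int | None = None) -> np.ndarray:
    """Positions[t, molecule, xyz] (nm) in the periodic box."""
    n_steps = cfg.n_steps if n_steps is None else n_steps
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_molecules)
    out = np.empty((n_steps, cfg.n_molecules, 3))
    for m in range(cfg.n_molecules):
        rng = np.random.default_rng(children[m])
        out[:, m, :] = _molecule_path(cfg, n_steps, rng).T
    return out


# ---------------------------------------------------------------------------
# triplet blinking
# ---------------------------------------------------------------------------

def _dwell_states(T, tau, dt, n_steps, rng):
    """Bright(True)/dark(False) per bin for one molecule.

    Continuous-time two-state chain with rates k_dark = T/τ_T (bright→dark)
    and k_bright = (1−T)/τ_T (dark→bright): stationary dark fraction T,
    relaxation time τ_T.  Dwell times rasterized to the bin grid.
    """
    if T == 0:
        return np.ones(n_steps, dtype=bool)
    k_dark = T / tau          # bright -> dark rate
    k_bright = (1.0 - T) / tau
    total_time = n_steps * dt
    s0 = rng.random() >= T    # stationary initial state, True = bright
    # alternating dwell rates: state of dwell i is s0 XOR (i odd)
    mean_cycle = 1.0 / k_dark + 1.0 / k_bright
    n_draw = int(2.0 * total_time / mean_cycle * 1.3 + 50)
    dwells = np.empty(0)
    while True:
        extra = rng.exponential(size=n_draw)
        i = dwells.size + np.arange(n_draw)
        bright = (i % 2 == 0) == s0
        extra /= np.where(bright, k_dark, k_bright)
        dwells = np.concatenate([dwells, extra])
        if dwells.sum() >= total_time:
            break
        n_draw = max(n_draw // 2, 50)
    edges = np.cumsum(dwells)
    bins = np.arange(n_steps) * dt
    idx = np.searchsorted(edges, bins, side="right")
    return (idx % 2 == 0) == s0


def triplet_states(cfg: SimConfig, n_steps: int | None = None) -> np.ndarray:
    """On/off[t, molecule] bright-state indicator."""
    if cfg.triplet_T > 0 and cfg.triplet_tau <= cfg.dt:
        raise ValueError("triplet_tau must exceed the bin width dt")
    n_steps = cfg.n_steps if n_steps is None else n_steps
    ss = np.random.SeedSequence((cfg.seed, 1))
    children = ss.spawn(cfg.n_molecules)
    out = np.empty((n_steps, cfg.n_molecules), dtype=bool)
    for m in range(cfg.n_molecules):
        rng = np.random.default_rng(children[m])
        out[:, m] = _dwell_states(cfg.triplet_T, cfg.triplet_tau, cfg.dt,
                                  n_steps, rng)
    return out


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _volume_lookup(vol: EffectiveVolume | tuple, positions: np.ndarray) -> np.ndarray:
    """Relative detection probability at positions (..., 3) in nm.

    ``vol`` may be an :class:`EffectiveVolume` (grid, trilinear
    interpolation, zero outside) or a tuple (omega_xy, omega_z) selecting
    the analytic 3-D Gaussian fast path.
    """
    x, y, z = positions[..., 0], positions[..., 1], positions[..., 2]
    if isinstance(vol, tuple):
        wxy, wz = vol
        return np.exp(-2.0 * ((x * x + y * y) / (wxy * wxy) + (z * z) / (wz * wz)))
    xs, ys, zs = vol.axes
    cx = (x - xs[0]) / vol.voxel[0]
    cy = (y - ys[0]) / vol.voxel[1]
    cz = (z - zs[0]) / vol.voxel[2]
    return map_coordinates(vol.detection, [cz.ravel(), cy.ravel(), cx.ravel()],
                           order=1, mode="constant", cval=0.0).reshape(x.shape)


def photon_trace(positions: np.ndarray, states: np.ndarray | None,
                 vol, cfg: SimConfig,
                 rng: np.random.Generator | None = None) -> PhotonTrace:
    """Poisson counts per bin from explicit trajectories and blink states."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    n_steps = positions.shape[0]
    rate = np.full(n_steps, cfg.background * cfg.dt)
    if positions.shape[1]:
        v = _volume_lookup(vol, positions)          # (t, mol)
        if states is not None:
            v = v * states
        rate += cfg.brightness0 * cfg.dt * v.sum(axis=1)
    if cfg.bleach_tau is not None:
        t = np.arange(n_steps) * cfg.dt
        rate *= np.exp(-t / cfg.bleach_tau)
    counts = rng.poisson(rate)
    return PhotonTrace(counts, cfg.dt, {"config": cfg})


def simulate_trace(cfg: SimConfig, vol, check_box: bool = True) -> PhotonTrace:
    """Full generator: trajectories + blinking + Poisson detection.

    Molecules are processed one at a time with per-molecule random
    streams, so the result is independent of batching and bit-reproducible
    for a given seed.  ``vol`` is an EffectiveVolume or an
    (omega_xy, omega_z) Gaussian fast-path tuple.
    """
    omega_z = vol[1] if isinstance(vol, tuple) else vol.omega_z
    if check_box and cfg.box < 6.0 * omega_z:
        warnings.warn("box smaller than 6·omega_z; ensemble may be depleted")
    n_steps = cfg.n_steps
    ss_traj = np.random.SeedSequence(cfg.seed).spawn(max(cfg.n_molecules, 1))
    ss_trip = np.random.SeedSequence((cfg.seed, 1)).spawn(max(cfg.n_molecules, 1))
    rate = np.full(n_steps, cfg.background * cfg.dt)
    for m in range(cfg.n_molecules):
        rng_t = np.random.default_rng(ss_traj[m])
        pos = _molecule_path(cfg, n_steps, rng_t)       # (3, t)
        v = _volume_lookup(vol, pos.T)
        if cfg.triplet_T > 0:
            rng_b = np.random.default_rng(ss_trip[m])
            v = v * _dwell_states(cfg.triplet_T, cfg.triplet_tau, cfg.dt,
                                  n_steps, rng_b)
        rate += cfg.brightness0 * cfg.dt * v
    if cfg.bleach_tau is not None:
        t = np.arange(n_steps) * cfg.dt
        rate *= np.exp(-t / cfg.bleach_tau)
    rng_p = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    counts = rng_p.poisson(rate)
    meta = {"config": cfg, "mean_rate": float(rate.mean() / cfg.dt)}
    if isinstance(vol, EffectiveVolume):
        meta["V_eff"] = vol.V_eff
        meta["expected_N"] = cfg.n_molecules * vol.V_eff / (cfg.box ** 3 * 1e-24)
    return PhotonTrace(counts, cfg.dt, meta)


# ---------------------------------------------------------------------------
# simulated microscope (AcquisitionInterface)
# ---------------------------------------------------------------------------

class SimulatedMicroscope:
    """Virtual AO STED-FCS instrument.

    Composes the z-STED pupil with a hidden ``true_aberration`` plus the
    user-applied correction state, propagates both beams, forms the
    effective volume at saturation ζ and simulates a photon trace.  Only
    the depletion path is aberrated by default; a static
    ``excitation_aberration`` can be added to emulate uncorrected
    excitation-path degradation.
    """

    def __init__(self, sim: SimConfig,
                 sted_cfg: OpticalConfig = OpticalConfig(),
                 exc_cfg: OpticalConfig = EXCITATION_CONFIG,
                 zeta: float = 8.0,
                 roi: FocalROI = FocalROI((1200.0, 1200.0, 2400.0),
                                          (20.0, 20.0, 40.0)),
                 pupil_samples: int = 64,
                 detection_wavelength: float = 685.0,
                 true_aberration: AberrationState | None = None,
                 excitation_aberration: AberrationState | None = None):
        self.sim = sim
        self.sted_cfg = sted_cfg
        self.exc_cfg = exc_cfg
        self.zeta = zeta
        self.roi = roi
        self.grid = PupilGrid(pupil_samples)
        self.true_aberration = true_aberration or AberrationState()
        self._acq_counter = 0
        flat = PhaseMap(np.zeros((pupil_samples, pupil_samples)), self.grid.mask)
        if excitation_aberration is not None:
            flat = compose_pupil(flat, excitation_aberration, exc_cfg, self.grid)
        # combined excitation x pinhole-filtered detection profile: both focal
        # fields are diffraction-limited confocal profiles at their wavelengths
        exc = focal_intensity(flat, exc_cfg, roi)
        det_cfg = OpticalConfig(wavelength=detection_wavelength,
                                numerical_aperture=exc_cfg.numerical_aperture,
                                n_immersion=exc_cfg.n_immersion,
                                pupil_samples=pupil_samples)
        det = focal_intensity(flat, det_cfg, roi)
        self.exc_psf = PSF3D(exc.intensity * det.intensity, roi.voxel, exc.axes,
                             {"combined_excitation_detection": True})
        self._sted_ref_peak = None
        self._vol_cache: dict = {}

    # -- optics ------------------------------------------------------------
    def build_volume(self, state: AberrationState, zeta: float | None = None
                     ) -> EffectiveVolume:
        """Effective volume for the composed (hidden + applied) aberration.

        ζ parameterizes the laser power through the *unaberrated* pattern;
        an aberrated pattern with a weaker focal peak depletes less, so
        the applied saturation scales with the raw peak-intensity ratio.
        """
        zeta = self.zeta if zeta is None else zeta
        total = self.true_aberration + state
        key = (round(zeta, 9),) + tuple(sorted(
            (k, round(v, 9)) for k, v in total.nonzero().items()))
        if key in self._vol_cache:
            return self._vol_cache[key]
        base = zsted_mask(self.grid)
        if self._sted_ref_peak is None:
            ref = focal_intensity(base, self.sted_cfg, self.roi)
            self._sted_ref_peak = ref.meta["peak_intensity"]
        pupil = compose_pupil(base, total, self.sted_cfg, self.grid)
        sted_psf = focal_intensity(pupil, self.sted_cfg, self.roi)
        zeta_eff = zeta * sted_psf.meta["peak_intensity"] / self._sted_ref_peak
        vol = effective_volume(self.exc_psf, sted_psf, zeta_eff)
        vol.meta["zeta_nominal"] = zeta
        if len(self._vol_cache) < 64:
            self._vol_cache[key] = vol
        return vol

    # -- acquisition -------------------------------------------------------
    def acquire(self, state: AberrationState, duration: float | None = None,
                zeta: float | None = None, seed: int | None = None) -> PhotonTrace:
        vol = self.build_volume(state, zeta)
        cfg = self.sim
        if duration is not None:
            cfg = replace(cfg, duration=duration)
        if seed is None:
            # fresh but deterministic sub-seed per acquisition
            seed = int(np.random.SeedSequence(
                (self.sim.seed, 3, self._acq_counter)).generate_state(1)[0] % (2**31))
            self._acq_counter += 1
        cfg = replace(cfg, seed=seed)
        trace = simulate_trace(cfg, vol, check_box=False)
        trace.meta["applied_state"] = state.nonzero()
        trace.meta["zeta"] = self.zeta if zeta is None else zeta
        return trace


# ---------------------------------------------------------------------------
# trace I/O: raw uint32 little-endian + JSON sidecar, CSV for small traces
# ---------------------------------------------------------------------------

def write_trace(trace: PhotonTrace, path):
    path = str(path)
    if path.endswith(".csv"):
        np.savetxt(path, np.column_stack([
            np.arange(trace.counts.size) * trace.dt, trace.counts]),
            delimiter=",", header="time_s,counts", comments="")
        return
    np.asarray(trace.counts, dtype="<u4").tofile(path)
    meta = {"dt": trace.dt, "n_bins": int(trace.counts.size),
            "duration": trace.duration}
    cfg = trace.meta.get("config")
    if cfg is not None:
        meta["config"] = {k: v for k, v in vars(cfg).items()
                          if isinstance(v, (int, float, str, bool, type(None)))}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trace(path) -> PhotonTrace:
    path = str(path)
    if path.endswith(".csv"):
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        dt = float(data[1, 0] - data[0, 0])
        return PhotonTrace(data[:, 1], dt, {"source": path})
    with open(path + ".json") as fh:
        meta = json.load(fh)
    counts = np.fromfile(path, dtype="<u4")
    return PhotonTrace(counts.astype(np.int64), float(meta["dt"]),
                       {"source": path, **meta})
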