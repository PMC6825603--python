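"""Effective observation volumes and the aspect-ratio calibration.

The effective fluorescence observation volume of a STED-FCS measurement is
the excitation/detection profile multiplied by the depletion survival
probability ``exp(-ζ·I_STED/I_max)``, where the saturation factor ζ stands
in for the STED laser power.  The volume is summarized by its Gaussian
dimensions: lateral/axial 1/e² radii ω_xy, ω_z and the aspect ratio
K = ω_z/ω_xy.

The empirical calibration ω_xy(K) (lateral shrinking of the observation
volume as depletion raises, normalized to the confocal value) is modelled
as a saturating exponential constrained to pass through (K_conf, 1):

    ω_norm(K) = w_inf + (1 - w_inf) · exp((K - K_conf)/κ)

Inverting this relation converts a measured lateral transit-time ratio
into the aspect ratio used by the coupled STED fitting model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import pi, sqrt, log

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

from .optics import PSF3D

__all__ = [
    "GaussianDims",
    "EffectiveVolume",
    "KCalibration",
    "effective_volume",
    "gaussian_dims",
    "fit_k_calibration",
    "k_from_transit_ratio",
]

#: FWHM of exp(-2u²/ω²) in units of ω.
FWHM_PER_OMEGA = sqrt(2.0 * log(2.0))

#: liters per cubic nanometer
L_PER_NM3 = 1e-24


@dataclass
class GaussianDims:
    omega_xy: float     # lateral 1/e² radius, nm
    omega_z: float      # axial 1/e² radius, nm
    fwhm_xy: float
    fwhm_z: float
    K: float            # omega_z / omega_xy
    flags: list = field(default_factory=list)


def _gauss1d(u, amp, u0, omega, offset):
    return amp * np.exp(-2.0 * (u - u0) ** 2 / omega ** 2) + offset


def _fit_profile(coords, profile):
    profile = np.asarray(profile, dtype=float)
    lo, hi = profile.min(), profile.max()
    u0 = coords[int(np.argmax(profile))]
    # half-width initial guess from the closest half-maximum crossings
    above = profile > (lo + 0.5 * (hi - lo))
    width = max((above.sum()) * abs(coords[1] - coords[0]), abs(coords[1] - coords[0]))
    p0 = [hi - lo, u0, width / FWHM_PER_OMEGA, lo]
    popt, _ = curve_fit(
        _gauss1d, coords, profile, p0=p0,
        bounds=([0.0, coords[0], 1e-3, 0.0],
                [4.0 * max(hi - lo, 1e-12), coords[-1], 10 * (coords[-1] - coords[0]),
                 max(hi, 1e-12)]),
        maxfev=10000,
    )
    return abs(popt[2])


def gaussian_dims(vol: np.ndarray, voxel, axes=None) -> GaussianDims:
    """1-D Gaussian fits to the axial/lateral profiles through the peak.

    ``vol`` is indexed (z, y, x).  Both 1/e² radii and FWHM values are
    reported; non-converging fits fall back to a second-moment estimate and
    are flagged.
    """
    vol = np.asarray(vol, dtype=float)
    nz, ny, nx = vol.shape
    if axes is None:
        axes = (
            (np.arange(nx) - nx // 2) * voxel[0],
            (np.arange(ny) - ny // 2) * voxel[1],
            (np.arange(nz) - nz // 2) * voxel[2],
        )
    xs, ys, zs = axes
    iz, iy, ix = np.unravel_index(np.argmax(vol), vol.shape)
    flags = []

    def fit(coords, profile, label):
        try:
            return _fit_profile(np.asarray(coords, float), profile)
        except Exception:
            flags.append(f"fit_failed_{label}")
            p = np.asarray(profile, float)
            p = p - p.min()
            if p.sum() <= 0:
                return float("nan")
            c = np.average(coords, weights=p)
            var = np.average((coords - c) ** 2, weights=p)
            return 2.0 * sqrt(max(var, 0.0))

    wx = fit(xs, vol[iz, iy, :], "x")
    wy = fit(ys, vol[iz, :, ix], "y")
    wz = fit(zs, vol[:, iy, ix], "z")
    omega_xy = 0.5 * (wx + wy)
    K = wz / omega_xy if omega_xy > 0 else float("nan")
    return GaussianDims(omega_xy, wz, FWHM_PER_OMEGA * omega_xy,
                        FWHM_PER_OMEGA * wz, K, flags)


@dataclass
class EffectiveVolume:
    """Relative detection probability grid with Gaussian summary dimensions."""

    detection: np.ndarray       # (z, y, x), max-normalized
    voxel: tuple
    axes: tuple
    omega_xy: float
    omega_z: float
    K: float
    V_eff: float                # liters, Gaussian-equivalent π^{3/2}·ω_xy²·ω_z
    V_occ: float = 0.0          # liters, occupancy volume (∫W)²/∫W² from the grid
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def effective_volume(exc: PSF3D, sted: PSF3D | None, saturation: float) -> EffectiveVolume:
    """Excitation profile × exponential depletion survival at saturation ζ.

    ``sted=None`` or ζ=0 gives the confocal volume.  Grids must match.
    ``exc`` is the combined excitation-detection (pinhole-filtered)
    profile.  The result is NOT re-normalized: a degraded depletion null
    suppresses the peak detection probability, i.e. aberrations cost
    signal, as they do on the instrument.
    """
    if saturation < 0:
        raise ValueError("saturation must be >= 0")
    det = exc.intensity.copy()
    if sted is not None and saturation > 0:
        if sted.intensity.shape != exc.intensity.shape or sted.voxel != exc.voxel:
            raise ValueError("excitation and depletion grids must match")
        smax = sted.intensity.max()
        det = det * np.exp(-saturation * sted.intensity / smax)
    dims = gaussian_dims(det, exc.voxel, exc.axes)
    v_eff = pi ** 1.5 * dims.omega_xy ** 2 * dims.omega_z * L_PER_NM3
    vox_nm3 = exc.voxel[0] * exc.voxel[1] * exc.voxel[2]
    v_occ = float(det.sum() ** 2 / (det * det).sum() * vox_nm3 * L_PER_NM3)
    return EffectiveVolume(det, exc.voxel, exc.axes, dims.omega_xy, dims.omega_z,
                           dims.K, v_eff, v_occ, dims.flags,
                           {"saturation": saturation,
                            "peak_detection": float(det.max())})


# ---------------------------------------------------------------------------
# K calibration
# ---------------------------------------------------------------------------

CALIBRATION_FORM = "w_inf + (1 - w_inf) * exp((K - K_conf)/kappa)"


@dataclass
class KCalibration:
    """Exponential model linking aspect ratio K to normalized lateral size."""

    points: np.ndarray          # (n, 2) columns (K, omega_norm)
    w_inf: float
    kappa: float
    K_conf: float
    fit_residual: float = 0.0
    form: str = CALIBRATION_FORM
    flags: list = field(default_factory=list)

    def omega(self, K):
        K = np.asarray(K, dtype=float)
        out = self.w_inf + (1.0 - self.w_inf) * np.exp((K - self.K_conf) / self.kappa)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path=None):
        payload = {
            "form": self.form,
            "params": {"w_inf": self.w_inf, "kappa": self.kappa,
                       "K_conf": self.K_conf},
            "fit_residual": self.fit_residual,
            "points": np.asarray(self.points).tolist(),
            "flags": list(self.flags),
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str,)) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        p = payload["params"]
        return cls(np.asarray(payload.get("points", [])), p["w_inf"], p["kappa"],
                   p["K_conf"], payload.get("fit_residual", 0.0),
                   payload.get("form", CALIBRATION_FORM),
                   payload.get("flags", []))


def identity_calibration(K_conf: float = 4.0) -> KCalibration:
    """Degenerate calibration with no lateral shrinking (ω_norm ≡ 1)."""
    return KCalibration(np.empty((0, 2)), 1.0, 1.0, K_conf,
                        flags=["identity"])


def fit_k_calibration(points, K_conf: float | None = None) -> KCalibration:
    """Least-squares fit of the exponential lateral-shrinking calibration.

    ``points`` is a sequence of (K, omega_norm) pairs including the
    confocal anchor (K_conf, 1).  If ``K_conf`` is not given, the K of the
    point with omega_norm closest to 1 is used.  Degenerate (constant)
    input returns a flagged identity calibration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (K, omega_norm) points")
    Ks, om = pts[:, 0], pts[:, 1]
    if K_conf is None:
        K_conf = float(Ks[int(np.argmin(np.abs(om - 1.0)))])
    if np.ptp(om) < 1e-9:
        return identity_calibration(K_conf)

    def resid(theta):
        w_inf, log_kappa = theta
        kappa = np.exp(log_kappa)
        return w_inf + (1.0 - w_inf) * np.exp((Ks - K_conf) / kappa) - om

    sol = least_squares(resid, x0=[max(min(om.min(), 0.99), 0.01), 0.0],
                        bounds=([0.0, -6.0], [0.999999, 5.0]))
    w_inf, kappa = float(sol.x[0]), float(np.exp(sol.x[1]))
    cal = KCalibration(pts, w_inf, kappa, float(K_conf),
                       fit_residual=float(np.sqrt(np.sum(sol.fun ** 2))))
    # the chosen form is monotone increasing in K by construction; flag if the
    # data itself is not
    order = np.argsort(Ks)
    if np.any(np.diff(om[order]) < -0.05):
        cal.flags.append("nonmonotone_points")
    return cal


def k_from_transit_ratio(tau_ratio: float, cal: KCalibration,
                         alpha: float = 1.0, K_min: float = 1.0,
                         return_flag: bool = False):
    """Invert the calibration: lateral transit-time ratio -> aspect ratio K.

    The anomalous transit scaling τ ∝ ω^{2/α} maps the transit-time ratio
    to an ω ratio via tau_ratio^{α/2}; the calibration is then inverted by
    monotone bracketing.  The result clamps to [K_min, K_conf]; clamped
    queries are flagged.
    """
    if tau_ratio <= 0:
        raise ValueError("tau_ratio must be positive")
    omega_ratio = tau_ratio ** (alpha / 2.0)
    flag = None
    if omega_ratio >= 1.0:
        K = cal.K_conf
        if omega_ratio > 1.0 + 1e-9:
            flag = "clamped_high"
    else:
        lo = cal.omega(K_min)
        if omega_ratio <= lo:
            K = K_min
            flag = "clamped_low"
        else:
            K = brentq(lambda k: cal.omega(k) - omega_ratio, K_min, cal.K_conf,
                       xtol=1e-12)
    if return_flag:
        return float(K), flag
    return float(K)
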