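"""ACF models and fitting for confocal and z-STED FCS.

The correlation model is the product of an anomalous 3-D Gaussian
diffusion term and a triplet-blinking term:

    G(τ) = G_T(τ) · G_D(τ)
    G_T(τ) = 1 + T/(1−T) · exp(−τ/τ_T)
    G_D(τ) = (1/N) · 1/(1+(τ/τ_xy)^α) · 1/sqrt(1+(τ/τ_xy)^α/K²) + δ

with apparent molecule number N, lateral transit time τ_xy, anomaly
exponent α, aspect ratio K = ω_z/ω_xy of the Gaussian-equivalent
observation volume, and offset δ.

Three fitting variants:

* ``fit_confocal``      — K pinned (conventionally 4), τ_T pinned, free
                          (N, τ_xy, T, δ) and optionally α.
* ``fit_sted_coupled``  — the coupled-aspect-ratio model: K is not a free
                          parameter but follows the lateral transit-time
                          ratio τ_xy/τ_xy,confocal through the empirical
                          exponential calibration.
* ``fit_sted_fixed_lateral`` — the legacy comparator: τ_xy pinned to the
                          confocal value, K free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .correlator import ACF
from .volume import KCalibration, k_from_transit_ratio

__all__ = [
    "FCSModelParams",
    "FitResult",
    "model_g",
    "fit_confocal",
    "fit_sted_coupled",
    "fit_sted_fixed_lateral",
    "residual_metric",
    "qc_long_lag",
    "tau_z",
    "concentration",
    "axial_shrink_ratio",
]

AVOGADRO = 6.02214076e23

#: δ is kept within this fraction of the amplitude to avoid degeneracy
#: with the long-lag tail.
DELTA_BOUND_FRACTION = 0.2


@dataclass
class FCSModelParams:
    N: float
    tau_xy: float               # s
    alpha: float = 1.0
    K: float = 4.0
    T: float = 0.0              # triplet amplitude
    tau_T: float = 12e-6        # s
    delta: float = 0.0

    def validate(self):
        if self.N <= 0 or self.tau_xy <= 0:
            raise ValueError("N and tau_xy must be positive")
        if not 0 < self.alpha <= 1.2:
            raise ValueError("alpha out of range (0, 1.2]")
        if self.K < 0.5:
            raise ValueError("K must be >= 0.5")
        if not 0 <= self.T < 1:
            raise ValueError("T must be in [0, 1)")
        return self

    def amplitude(self) -> float:
        """Zero-lag model limit minus the offset."""
        return (1.0 / (1.0 - self.T)) * (1.0 / self.N + self.delta) - self.delta


@dataclass
class FitResult:
    params: FCSModelParams
    fixed_mask: tuple = ()
    residual_norm: float = 0.0
    stderrs: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_json_dict(self):
        return {
            "params": vars(self.params),
            "fixed": list(self.fixed_mask),
            "residual_norm": self.residual_norm,
            "stderrs": self.stderrs,
            "flags": list(self.flags),
        }


def model_g(tau, p: FCSModelParams):
    """Evaluate G(τ) = G_T(τ)·G_D(τ) for τ > 0."""
    p.validate()
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    x = (tau / p.tau_xy) ** p.alpha
    gd = (1.0 / p.N) / (1.0 + x) / np.sqrt(1.0 + x / (p.K * p.K)) + p.delta
    gt = 1.0 + p.T / (1.0 - p.T) * np.exp(-tau / p.tau_T)
    return gd * gt


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _weights(acf: ACF, weighted: bool):
    if not weighted or acf.stderr is None:
        return np.ones_like(acf.G)
    floor = np.percentile(acf.stderr[acf.stderr > 0], 10) if np.any(acf.stderr > 0) else 1.0
    return 1.0 / np.maximum(acf.stderr, floor)


def _initial_guesses(acf: ACF):
    amp = float(np.mean(acf.G[: max(2, acf.G.size // 20)]))
    amp = max(amp, 1e-6)
    target = 0.5 * amp
    below = np.nonzero(acf.G <= target)[0]
    tau0 = float(acf.lags[below[0]]) if below.size else float(acf.lags[-1] / 10)
    return amp, max(tau0, float(acf.lags[0]))


def _run_fit(acf: ACF, params: lmfit.Parameters, evaluate, fixed_mask,
             weighted: bool) -> FitResult:
    w = _weights(acf, weighted)

    def resid(ps):
        return (evaluate(ps, acf.lags) - acf.G) * w

    flags = []
    try:
        out = lmfit.minimize(resid, params, method="leastsq")
        if not out.success:
            flags.append("non_convergence")
        final = out.params
    except Exception:
        flags.append("non_convergence")
        out = None
        final = params

    p = _params_to_model(final)
    stderrs = {}
    if out is not None:
        for name, par in out.params.items():
            if par.vary and par.stderr is not None:
                stderrs[name] = float(par.stderr)
    model = evaluate(final, acf.lags)
    residual_norm = float(np.sum((acf.G - model) ** 2))
    return FitResult(p, tuple(fixed_mask), residual_norm, stderrs, flags)


def _params_to_model(ps: lmfit.Parameters) -> FCSModelParams:
    return FCSModelParams(
        N=ps["N"].value, tau_xy=ps["tau_xy"].value, alpha=ps["alpha"].value,
        K=ps["K"].value, T=ps["T"].value, tau_T=ps["tau_T"].value,
        delta=ps["delta"].value,
    )


def _base_params(acf: ACF, K: float, tau_T: float, alpha: float,
                 alpha_free: bool, triplet_free: bool = True) -> lmfit.Parameters:
    amp, tau0 = _initial_guesses(acf)
    ps = lmfit.Parameters()
    ps.add("N", value=1.0 / amp, min=1e-6)
    ps.add("tau_xy", value=tau0, min=float(acf.lags[0]) / 10,
           max=float(acf.lags[-1]) * 10)
    ps.add("alpha", value=alpha, min=0.2, max=1.2, vary=alpha_free)
    ps.add("K", value=K, min=0.5, max=50.0, vary=False)
    ps.add("T", value=0.1 if triplet_free else 0.0, min=0.0, max=0.8,
           vary=triplet_free)
    ps.add("tau_T", value=tau_T, vary=False)
    bound = DELTA_BOUND_FRACTION * amp
    ps.add("delta", value=0.0, min=-bound, max=bound)
    return ps


def fit_confocal(acf: ACF, K_fixed: float = 4.0, tau_T: float = 12e-6,
                 alpha: float = 1.0, alpha_free: bool = False,
                 triplet_free: bool = True, weighted: bool = True) -> FitResult:
    """Weighted least-squares fit of the confocal ACF with pinned K.

    K defaults to the conventional confocal aspect ratio of 4; the triplet
    correlation time is pinned (12 µs solution preset, 5 µs cell preset).
    """
    if acf.lags.size < 10 or acf.lags[-1] / acf.lags[0] < 100:
        raise ValueError("ACF must have >= 10 lags spanning >= 2 decades")
    ps = _base_params(acf, K_fixed, tau_T, alpha, alpha_free, triplet_free)

    def evaluate(params, lags):
        return model_g(lags, _params_to_model(params))

    fixed = ["K", "tau_T"] + ([] if alpha_free else ["alpha"]) \
        + ([] if triplet_free else ["T"])
    return _run_fit(acf, ps, evaluate, fixed, weighted)


def fit_sted_coupled(acf: ACF, confocal: FitResult, cal: KCalibration,
                     alpha: float | None = None, weighted: bool = True,
                     K_min: float = 1.0) -> FitResult:
    """Coupled-aspect-ratio STED fit.

    Free parameters are (N, τ_xy, T, δ); at every model evaluation the
    aspect ratio is derived from the transit-time ratio
    τ_xy/τ_xy,confocal through the lateral-shrinking calibration, so the
    observation-volume shape is described by one parameter instead of two.
    α and τ_T are inherited from the confocal fit.
    """
    if "non_convergence" in confocal.flags:
        raise ValueError("confocal reference fit did not converge")
    if "identity" in cal.flags or cal.w_inf >= 1.0 - 1e-9:
        # no lateral shrinking: the transit-time ratio carries no volume-shape
        # information and the coupled model degenerates to the legacy
        # fixed-lateral-transit model
        result = fit_sted_fixed_lateral(acf, confocal, weighted=weighted)
        result.flags.append("identity_calibration_fallback")
        return result
    alpha = confocal.params.alpha if alpha is None else alpha
    tau_conf = confocal.params.tau_xy
    ps = _base_params(acf, cal.K_conf, confocal.params.tau_T, alpha,
                      alpha_free=False)
    clamp_seen = []

    def evaluate(params, lags):
        p = _params_to_model(params)
        K, flag = k_from_transit_ratio(p.tau_xy / tau_conf, cal, alpha,
                                       K_min=K_min, return_flag=True)
        if flag:
            clamp_seen.append(flag)
        p = replace(p, K=K, alpha=alpha)
        return model_g(lags, p)

    result = _run_fit(acf, ps, evaluate, ["alpha", "tau_T", "K:coupled"],
                      weighted)
    K, flag = k_from_transit_ratio(result.params.tau_xy / tau_conf, cal,
                                   alpha, K_min=K_min, return_flag=True)
    result.params = replace(result.params, K=K, alpha=alpha)
    if flag:
        result.flags.append(flag)
    return result


def fit_sted_fixed_lateral(acf: ACF, confocal: FitResult,
                           weighted: bool = True) -> FitResult:
    """Legacy STED fit: τ_xy pinned to the confocal value, K free."""
    if "non_convergence" in confocal.flags:
        raise ValueError("confocal reference fit did not converge")
    cp = confocal.params
    ps = _base_params(acf, cp.K, cp.tau_T, cp.alpha, alpha_free=False)
    ps["tau_xy"].set(value=cp.tau_xy, vary=False)
    ps["K"].set(vary=True)

    def evaluate(params, lags):
        return model_g(lags, _params_to_model(params))

    return _run_fit(acf, ps, evaluate, ["tau_xy", "alpha", "tau_T"], weighted)


# ---------------------------------------------------------------------------
# QC and derived quantities
# ---------------------------------------------------------------------------

def residual_metric(acf: ACF, fit: FitResult) -> float:
    """Sum of squared fit residuals normalized by the squared amplitude."""
    amp = fit.params.amplitude()
    if amp == 0:
        raise ValueError("zero fitted amplitude")
    model = model_g(acf.lags, fit.params)
    return float(np.sum((acf.G - model) ** 2) / (amp * amp))


def qc_long_lag(acf: ACF, fit: FitResult | None = None,
                tail_decades: float = 1.0, threshold: float = 0.1) -> bool:
    """Pass/fail check that the ACF converges to ~0 at long lags.

    Fails when the mean G over the last ``tail_decades`` of the lag range
    exceeds ``threshold`` times the amplitude.  Curves failing this check
    are the ones affected by bleaching or other slow artefacts.
    """
    if acf.lags[-1] / acf.lags[0] < 1e3:
        raise ValueError("ACF must span at least 3 decades for tail QC")
    if np.isinf(threshold):
        return True
    tail = acf.lags >= acf.lags[-1] / 10 ** tail_decades
    if fit is not None:
        amp = fit.params.amplitude()
    else:
        amp = float(np.mean(acf.G[: max(2, acf.G.size // 20)]))
    return bool(abs(np.mean(acf.G[tail])) <= threshold * abs(amp))


def tau_z(fit: FitResult) -> float:
    """Axial transit time τ_z = K^{2/α} · τ_xy (K² for Brownian)."""
    p = fit.params
    return p.K ** (2.0 / p.alpha) * p.tau_xy


def concentration(N: float, V_eff: float) -> float:
    """Molar concentration from occupancy N and effective volume (liters)."""
    if V_eff <= 0:
        raise ValueError("V_eff must be positive")
    return N / (AVOGADRO * V_eff)


def axial_shrink_ratio(sted: FitResult, confocal: FitResult) -> float:
    """Estimated ω_z/ω_z,confocal from a STED fit and its confocal reference.

    ω_xy scales as (τ_xy ratio)^{α/2} and ω_z = K·ω_xy, with the confocal
    aspect ratio taken from the confocal fit convention.
    """
    alpha = sted.params.alpha
    ratio_xy = (sted.params.tau_xy / confocal.params.tau_xy) ** (alpha / 2.0)
    return ratio_xy * sted.params.K / confocal.params.K
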