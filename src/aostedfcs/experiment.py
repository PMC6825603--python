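"""Experiment configuration, orchestration and result bundles.

An experiment mirrors the standard measurement pattern: (optionally) run
the sensorless AO schedule against a simulated sample with an injected
aberration, then record measurement traces over a ladder of depletion
saturation factors ζ with and without the determined correction,
correlate and fit each trace, and tabulate (N, ω_z/ω_z0, residual metric)
per ζ and AO state.

All lengths are nm, times s, phase amplitudes rad rms; ζ is the
dimensionless stand-in for STED laser power.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import MetricConfig, run_schedule
from .correlator import acf_to_csv, acf_with_stderr
from .fcsmodels import (axial_shrink_ratio, fit_confocal, fit_sted_coupled,
                        residual_metric)
from .moments import metric_from_trace
from .optics import AberrationState, FocalROI, OpticalConfig
from .photons import SimConfig, SimulatedMicroscope, write_trace
from .volume import fit_k_calibration, identity_calibration

__all__ = ["ExperimentConfig", "load_config", "save_config", "run_experiment"]

_ALLOWED_TOP = {"optics", "excitation", "sim", "schedule", "fitting",
                "zeta_ladder", "true_aberration", "seeds", "measurement_time",
                "ao", "name"}


@dataclass
class ExperimentConfig:
    name: str = "experiment"
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    excitation: OpticalConfig = field(
        default_factory=lambda: OpticalConfig(wavelength=640.0))
    sim: SimConfig = field(default_factory=SimConfig)
    schedule: str = "solution"
    ao: bool = True
    fitting: dict = field(default_factory=lambda: {
        "K_confocal": 4.0, "tau_T": 12e-6, "alpha": 1.0})
    zeta_ladder: tuple = (0.0, 1.0, 2.0, 4.0)
    true_aberration: dict = field(default_factory=dict)
    seeds: tuple = (1,)
    measurement_time: float = 30.0     # s per FCS trace

    def config_hash(self) -> str:
        payload = json.dumps(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = {}
    for key, cls in (("optics", OpticalConfig), ("excitation", OpticalConfig),
                     ("sim", SimConfig)):
        if key in raw:
            section = raw[key]
            fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(section) - fields
            if bad:
                raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
            kwargs[key] = cls(**section)
    for key in ("schedule", "ao", "fitting", "true_aberration", "name",
                "measurement_time"):
        if key in raw:
            kwargs[key] = raw[key]
    if "zeta_ladder" in raw:
        kwargs["zeta_ladder"] = tuple(float(z) for z in raw["zeta_ladder"])
    if "seeds" in raw:
        kwargs["seeds"] = tuple(int(s) for s in raw["seeds"])
    return ExperimentConfig(**kwargs)


def save_config(cfg: ExperimentConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(_as_plain(cfg), fh, sort_keys=False)


def run_experiment(cfg: ExperimentConfig, outdir=None,
                   metric_cfg: MetricConfig = MetricConfig()) -> dict:
    """Simulate the full AO-on/AO-off STED-FCS measurement series.

    Returns a bundle with the correction state, the per-(ζ, AO) fit table
    and the raw objects; if ``outdir`` is given, traces, ACFs, fits and a
    summary CSV are written there.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    scope = SimulatedMicroscope(
        cfg.sim, sted_cfg=cfg.optics, exc_cfg=cfg.excitation,
        true_aberration=AberrationState(dict(cfg.true_aberration)))

    correction = AberrationState()
    ao_log: list = []
    if cfg.ao and cfg.true_aberration is not None:
        correction, ao_log = run_schedule(cfg.schedule, scope.acquire,
                                          metric_cfg)

    fit_cfg = cfg.fitting
    rows = []
    records = {}
    zetas = sorted(set(cfg.zeta_ladder))
    if 0.0 not in zetas:
        zetas = [0.0] + zetas

    # empirical lateral-shrinking calibration from the corrected volumes
    dims = {z: scope.build_volume(correction, zeta=z) for z in zetas}
    conf = dims[0.0]
    points = [(dims[z].K, dims[z].omega_xy / conf.omega_xy) for z in zetas]
    try:
        cal = fit_k_calibration(points, K_conf=conf.K)
    except ValueError:
        cal = identity_calibration(conf.K)

    for ao_on in ((True, False) if cfg.ao else (False,)):
        state = correction if ao_on else AberrationState()
        conf_trace = scope.acquire(state, duration=cfg.measurement_time,
                                   zeta=0.0)
        conf_acf = acf_with_stderr(conf_trace)
        conf_fit = fit_confocal(conf_acf, K_fixed=fit_cfg.get("K_confocal", 4.0),
                                tau_T=fit_cfg.get("tau_T", 12e-6),
                                alpha=fit_cfg.get("alpha", 1.0))
        for z in zetas:
            if z == 0.0:
                fit, acf, trace = conf_fit, conf_acf, conf_trace
            else:
                trace = scope.acquire(state, duration=cfg.measurement_time,
                                      zeta=z)
                acf = acf_with_stderr(trace)
                fit = fit_sted_coupled(acf, conf_fit, cal)
            label = f"zeta{z:g}_ao{'on' if ao_on else 'off'}"
            records[label] = (trace, acf, fit)
            rows.append({
                "zeta": z, "ao": ao_on, "N": fit.params.N,
                "tau_xy": fit.params.tau_xy, "K": fit.params.K,
                "omega_z_ratio": (1.0 if z == 0.0
                                  else axial_shrink_ratio(fit, conf_fit)),
                "residual_metric": residual_metric(acf, fit),
                "metric_N": metric_from_trace(trace, metric_cfg.bin_factor,
                                              metric_cfg.n_splits).value,
            })
            if outdir is not None:
                write_trace(trace, outdir / f"trace_{label}.bin")
                acf_to_csv(acf, outdir / f"acf_{label}.csv",
                           provenance=f"{cfg.name} {label} hash={cfg.config_hash()}")
                with open(outdir / f"fit_{label}.json", "w") as fh:
                    json.dump(fit.to_json_dict(), fh, indent=1)

    summary = pd.DataFrame(rows)
    bundle = {"correction": correction, "ao_log": ao_log, "summary": summary,
              "records": records, "calibration": cal,
              "config_hash": cfg.config_hash()}
    if outdir is not None:
        summary.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "correction.json", "w") as fh:
            json.dump({"modes": correction.nonzero(),
                       "config_hash": cfg.config_hash()}, fh, indent=1)
        with open(outdir / "ao_log.jsonl", "w") as fh:
            for scan in ao_log:
                fh.write(json.dumps({
                    "mode": scan.mode_id,
                    "biases": list(np.asarray(scan.biases)),
                    "metric": [m.value if np.isfinite(m.value) else None
                               for m in scan.metric],
                    "optimum": scan.optimum, "flags": scan.flags}) + "\n")
    return bundle
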