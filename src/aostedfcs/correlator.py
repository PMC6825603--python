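"""Intensity autocorrelation: direct evaluation and multiple-tau scheme.

The normalized ACF of a photon trace I(t) is

    G(τ) = <δI(t) δI(t+τ)> / <I(t)>²,   δI = I − <I>,

with <·> the time average over the trace (population statistics).  The
direct evaluator computes this exactly at integer-bin lags and serves as
the oracle; the multiple-tau evaluator produces the usual logarithmically
spaced lag grid, pairwise-averaging the trace after each level of m/2
lags.  Sub-trace splitting gives per-lag dispersion estimates, and the
local-averaging bleaching correction detrends slow brightness decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .photons import PhotonTrace

__all__ = [
    "ACF",
    "direct_acf",
    "multipletau_acf",
    "split_subtraces",
    "average_acfs",
    "acf_with_stderr",
    "bleach_correct",
    "acf_to_csv",
    "acf_from_csv",
]


@dataclass
class ACF:
    lags: np.ndarray                      # s, strictly increasing, > 0
    G: np.ndarray
    stderr: np.ndarray | None = None      # per-lag dispersion across sub-traces
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be non-negative")


def _eq1(signal: np.ndarray, k: int, mean: float) -> float:
    d = signal - mean
    n = signal.size
    return float(np.dot(d[: n - k], d[k:]) / (n - k)) / (mean * mean)


def direct_acf(trace: PhotonTrace, lags) -> ACF:
    """Exact normalized autocorrelation at the requested integer-bin lags."""
    signal = np.asarray(trace.counts, dtype=float)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1):
        raise ValueError("lags must be >= 1 bin")
    if lags.max() >= signal.size // 2:
        raise ValueError("max lag must be below half the trace length")
    mean = signal.mean()
    if mean == 0:
        raise ValueError("zero-mean trace: normalization undefined")
    G = np.array([_eq1(signal, int(k), mean) for k in lags])
    return ACF(lags * trace.dt, G, meta={"estimator": "direct"})


def multipletau_acf(trace: PhotonTrace, m: int = 16) -> ACF:
    """Multiple-tau ACF with coarsening block m.

    Level 0 evaluates lags 1..m on the raw trace; each further level
    pairwise-averages the trace (dropping a trailing odd bin) and
    evaluates lags m/2+1..m in coarsened units, doubling the lag spacing.
    Each level is normalized by the coarsened trace's own mean, so the
    values coincide exactly with the direct estimator applied to the
    binned trace.
    """
    if m % 2 != 0 or m < 4:
        raise ValueError("m must be even and >= 4")
    signal = np.asarray(trace.counts, dtype=float)
    if signal.size < 2 * m:
        raise ValueError("trace must contain at least 2·m bins")
    if signal.mean() == 0:
        raise ValueError("zero-mean trace: normalization undefined")

    lag_bins, G = [], []
    mean = signal.mean()
    for k in range(1, m + 1):
        if k >= signal.size // 2:
            break
        lag_bins.append(k)
        G.append(_eq1(signal, k, mean))

    level = 1
    while True:
        n2 = signal.size // 2
        if n2 < 2 * m:
            break
        signal = 0.5 * (signal[: 2 * n2 : 2] + signal[1 : 2 * n2 : 2])
        mean = signal.mean()
        scale = 2 ** level
        stop = False
        for k in range(m // 2 + 1, m + 1):
            if k >= signal.size // 2:
                stop = True
                break
            lag_bins.append(k * scale)
            G.append(_eq1(signal, k, mean))
        if stop:
            break
        level += 1

    lag_bins = np.asarray(lag_bins)
    return ACF(lag_bins * trace.dt, np.asarray(G),
               meta={"estimator": "multipletau", "m": m})


def split_subtraces(trace: PhotonTrace, k: int) -> list:
    """k contiguous equal-length sub-traces; the remainder is dropped."""
    if k < 2:
        raise ValueError("need k >= 2 parts")
    n = trace.counts.size // k
    if n < 1:
        raise ValueError("more parts than bins")
    return [PhotonTrace(trace.counts[i * n : (i + 1) * n], trace.dt,
                        {**trace.meta, "subtrace": i}) for i in range(k)]


def average_acfs(acfs: list) -> ACF:
    """Mean ACF and per-lag standard deviation across sub-trace ACFs."""
    n_lags = min(a.lags.size for a in acfs)
    lags = acfs[0].lags[:n_lags]
    stack = np.stack([a.G[:n_lags] for a in acfs])
    return ACF(lags, stack.mean(axis=0), stack.std(axis=0, ddof=0),
               meta={"estimator": acfs[0].meta.get("estimator"),
                     "n_subtraces": len(acfs)})


def acf_with_stderr(trace: PhotonTrace, splits: int = 5, m: int = 16) -> ACF:
    """Multiple-tau ACF averaged over contiguous sub-traces with dispersion."""
    parts = split_subtraces(trace, splits)
    return average_acfs([multipletau_acf(p, m) for p in parts])


def bleach_correct(trace: PhotonTrace, window: float) -> PhotonTrace:
    """Local-averaging detrend for photobleaching.

    With f(t) the moving-window local mean, the corrected (real-valued)
    trace is  I_c = I/sqrt(f/f0) + f0·(1 − sqrt(f/f0)),  which restores a
    flat local mean at f(0) while preserving the local fluctuation-to-mean
    ratio.
    """
    w = int(round(window / trace.dt))
    if w < 2 or w >= trace.counts.size:
        raise ValueError("window must cover >1 bin and be below the duration")
    signal = np.asarray(trace.counts, dtype=float)
    f = uniform_filter1d(signal, size=w, mode="nearest")
    if np.any(f <= 0):
        raise ValueError("non-positive local mean; cannot bleach-correct")
    f0 = f[min(w // 2, f.size - 1)]   # first fully interior window
    root = np.sqrt(f / f0)
    corrected = signal / root + f0 * (1.0 - root)
    return PhotonTrace(corrected, trace.dt,
                       {**trace.meta, "bleach_corrected": True,
                        "bleach_window_s": window})


def acf_to_csv(acf: ACF, path, provenance: str = ""):
    df = pd.DataFrame({"lag_s": acf.lags, "G": acf.G})
    if acf.stderr is not None:
        df["stderr"] = acf.stderr
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"# estimator={acf.meta.get('estimator', 'unknown')}\n")
        df.to_csv(fh, index=False)


def acf_from_csv(path) -> ACF:
    df = pd.read_csv(path, comment="#")
    stderr = df["stderr"].to_numpy() if "stderr" in df else None
    return ACF(df["lag_s"].to_numpy(), df["G"].to_numpy(), stderr,
               meta={"source": str(path)})
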