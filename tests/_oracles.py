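"""Independent brute-force references used by several test modules."""

import numpy as np


def binned_direct_reference(trace, m=16):
    """Brute-force multiple-tau reference: explicit pairwise averaging plus
    the exact normalized-ACF formula per level."""
    signal = np.asarray(trace.counts, float)
    lags, G = [], []

    def eq1(sig, k):
        mu = sig.mean()
        d = sig - mu
        return np.dot(d[:-k], d[k:]) / (d.size - k) / mu**2

    for k in range(1, m + 1):
        if k < signal.size // 2:
            lags.append(k)
            G.append(eq1(signal, k))
    level = 1
    while True:
        n2 = signal.size // 2
        if n2 < 2 * m:
            break
        signal = 0.5 * (signal[:2 * n2:2] + signal[1:2 * n2:2])
        stop = False
        for k in range(m // 2 + 1, m + 1):
            if k >= signal.size // 2:
                stop = True
                break
            lags.append(k * 2**level)
            G.append(eq1(signal, k))
        if stop:
            break
        level += 1
    return np.asarray(lags) * trace.dt, np.asarray(G)
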