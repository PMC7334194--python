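"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np


def harmonic_number(n_chromosomes: int) -> float:
    """Watterson's a_n = sum_{i=1}^{n-1} 1/i for a sample of ``n_chromosomes``."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n_chromosomes)))


def rolling_mean(values, window: int) -> np.ndarray:
    """Centered rolling mean, truncated (not padded) at the edges.

    For window w, position i averages values[max(0, i-h) : i+h+1] with
    h = w // 2, so edge estimates use fewer points rather than NaN.
    """
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    h = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        out[i] = x[lo:hi].mean()
    return out


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent RNG streams from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
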