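"""Posterior summaries: means, SDs, shortest HPD intervals, diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest empirical interval containing ``level`` of the draws.

    Scans every contiguous window of ``ceil(level * n)`` order statistics
    and returns the narrowest; for a constant chain the interval collapses
    to a point.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(level * n))
    k = min(max(k, 1), n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def geweke_z(samples: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means.

    Advisory only: |z| well above 2 suggests the chain has not settled.
    Uses simple batch-variance estimates of the spectral density at zero.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n) :]

    def batch_var(v: np.ndarray) -> float:
        nb = max(len(v) // 20, 1)
        means = [v[i * nb : (i + 1) * nb].mean() for i in range(len(v) // nb)]
        if len(means) < 2:
            return float(np.var(v) / len(v))
        return float(np.var(means, ddof=1) / len(means))

    denom = np.sqrt(batch_var(a) + batch_var(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def posterior_summary(
    chain, level: float = 0.95, min_samples: int = 100
) -> pd.DataFrame:
    """Mean, SD, and shortest HPD interval per variance component.

    ``chain`` is a :class:`~heatnorm.mixed_model.gibbs.PosteriorChain` (or
    any object with a ``samples`` DataFrame).  Raises ``ValueError`` when
    fewer than ``min_samples`` draws were retained.
    """
    df = chain.samples if hasattr(chain, "samples") else chain
    if len(df) < min_samples:
        raise ValueError(
            f"chain too short for summaries: {len(df)} < {min_samples} retained draws"
        )
    rows = []
    for col in df.columns:
        x = df[col].to_numpy()
        lo, hi = hpd_interval(x, level)
        rows.append((col, x.mean(), x.std(ddof=1), lo, hi, geweke_z(x)))
    return pd.DataFrame(
        rows, columns=["component", "mean", "sd", "hpd_low", "hpd_high", "geweke_z"]
    )
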