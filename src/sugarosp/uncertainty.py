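"""Error estimation for correlated time series.

Sequential frames of a Monte Carlo or molecular-dynamics trajectory are
correlated, so the naive standard error sqrt(var/n) underestimates the
uncertainty of a time average.  The variance of the mean is inflated by the
statistical inefficiency g = 1 + 2*tau, where tau is the integrated
autocorrelation time of the normalized autocorrelation function, giving
stderr = sqrt(g * var / n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stereo import ThermoConditions

__all__ = [
    "CorrelatedSeriesStats",
    "autocorrelation_stats",
    "propagate_through_zwanzig",
    "combine_weighted_errors",
]


@dataclass(frozen=True)
class CorrelatedSeriesStats:
    n: int
    mean: float
    variance: float
    tau: float  # integrated autocorrelation time, frames
    g: float  # statistical inefficiency, g = 1 + 2 tau, >= 1
    stderr: float  # sqrt(g * variance / n)


def _normalized_acf(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocorrelation estimate via FFT, normalized to acf[0] = 1."""
    n = x.size
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n] / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def autocorrelation_stats(series) -> CorrelatedSeriesStats:
    """Mean, variance and correlated-series standard error of the mean.

    tau is the sum of the normalized autocorrelation function over positive
    lags, truncated at its first non-positive value (initial-positive-sequence
    rule); g is floored at 1.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if var == 0.0:
        return CorrelatedSeriesStats(n, mean, 0.0, 0.0, 1.0, 0.0)
    acf = _normalized_acf(x)
    pos = acf[1:]
    stop = np.argmax(pos <= 0.0) if np.any(pos <= 0.0) else pos.size
    tau = float(pos[:stop].sum())
    g = max(1.0, 1.0 + 2.0 * tau)
    stderr = float(np.sqrt(g * var / n))
    return CorrelatedSeriesStats(n, mean, var, tau, g, stderr)


def propagate_through_zwanzig(exp_stats: CorrelatedSeriesStats,
                              conditions: ThermoConditions) -> float:
    """First-order error of dG = -kBT ln(mean w) from the stats of w.

    The relative error of the exponential average propagates through the
    logarithm: delta(dG) = kBT * stderr(w) / mean(w).  Invariant under the
    log-sum-exp shift because both mean and stderr scale identically.
    """
    if exp_stats.mean <= 0:
        raise ValueError("mean of an exponential series must be positive")
    return conditions.kBT * exp_stats.stderr / exp_stats.mean


def combine_weighted_errors(errors, weights) -> float:
    """Normalized-weight linear combination of individual standard errors.

    Weights are the Boltzmann factors exp(-dG_i/kBT) of the individual
    estimates, so well-sampled (low dG) references dominate the combined
    uncertainty, mirroring the exponential combination of the values.
    """
    e = np.asarray(errors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if e.shape != w.shape:
        raise ValueError("errors and weights must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero")
    return float((w * e).sum() / total)
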