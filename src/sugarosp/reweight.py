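"""Umbrella reweighting of observables and the reactive-pose criterion.

Ensemble averages of any per-frame property Q for a real compound i are
recovered from reference-ensemble frames via

    <Q>_i = <Q exp(-dH/kBT)>_R / <exp(-dH/kBT)>_R .

Applied to the indicator 1[r < 0.3 nm] of a probe hydrogen-to-acceptor
distance this yields the fraction of catalytically reactive poses per
stereoisomer.  Hydrogens are implicit in a united-atom model, so a probe
hydrogen is placed geometrically before the distance is measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .stereo import ThermoConditions
from .uncertainty import autocorrelation_stats

__all__ = [
    "ReweightedAverage",
    "reweighted_average",
    "reactive_fraction",
    "place_united_hydrogen",
    "UnboundFlag",
    "flag_unbound",
    "REACTIVE_CUTOFF_NM",
]

#: Hydride-transfer distance criterion, nm (strict inequality r < cutoff).
REACTIVE_CUTOFF_NM = 0.3


@dataclass(frozen=True)
class ReweightedAverage:
    value: float
    stderr: float
    n_frames: int
    unsampled: bool = False


def reweighted_average(q: np.ndarray, dH: np.ndarray,
                       conditions: ThermoConditions) -> ReweightedAverage:
    """<Q>_i from reference frames, with a correlated-series error bar.

    The error uses the delta method on the ratio of time averages: the
    stderr of the series w*(Q - <Q>_i)/mean(w) estimates the uncertainty of
    the reweighted mean including frame-to-frame correlation.
    """
    q = np.asarray(q, dtype=float).ravel()
    dH = np.asarray(dH, dtype=float).ravel()
    if q.shape != dH.shape:
        raise ValueError("property and dH series must be aligned")
    if q.size < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(q)):
        raise ValueError("property series must be finite")
    kBT = conditions.kBT
    log_w = -dH / kBT
    if not np.any(np.isfinite(log_w)):
        return ReweightedAverage(math.nan, 0.0, q.size, unsampled=True)
    shift = log_w[np.isfinite(log_w)].max()
    w = np.exp(log_w - shift)
    total = w.sum()
    if total == 0.0:
        return ReweightedAverage(math.nan, 0.0, q.size, unsampled=True)
    value = float((q * w).sum() / total)
    stderr = 0.0
    if q.size >= 10:
        resid = w * (q - value) / w.mean()
        stderr = autocorrelation_stats(resid).stderr
    return ReweightedAverage(value, stderr, q.size)


def reactive_fraction(distances: np.ndarray, dH: np.ndarray,
                      conditions: ThermoConditions,
                      cutoff: float = REACTIVE_CUTOFF_NM) -> ReweightedAverage:
    """Reweighted fraction of frames with probe distance strictly below
    ``cutoff`` (boundary equality counts as non-reactive)."""
    r = np.asarray(distances, dtype=float).ravel()
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    return reweighted_average((r < cutoff).astype(float), dH, conditions)


def place_united_hydrogen(carbon: np.ndarray, neighbors: np.ndarray,
                          bond_length: float = 0.1) -> np.ndarray:
    """Implicit-hydrogen position at a united CH center.

    The C-H bond points along the negated sum of the unit vectors from the
    carbon to its three heavy neighbors (ideal tetrahedral geometry), scaled
    to ``bond_length`` (nm).
    """
    c = np.asarray(carbon, dtype=float)
    nb = np.asarray(neighbors, dtype=float)
    if c.shape != (3,) or nb.shape != (3, 3):
        raise ValueError("need one carbon and exactly three neighbor positions")
    v = nb - c
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate geometry: neighbor coincides with carbon")
    direction = -(v / norms[:, None]).sum(axis=0)
    d = np.linalg.norm(direction)
    if d < 1e-10:
        raise ValueError("degenerate geometry: neighbor directions cancel")
    return c + bond_length * direction / d


@dataclass(frozen=True)
class UnboundFlag:
    """Keep/discard decision for a trajectory whose ligand may have left the
    binding site."""

    keep: bool
    first_violation_ps: float | None  # onset of the first sustained excursion
    channel: str | None = None


def flag_unbound(monitors: dict[str, np.ndarray], dt_ps: float,
                 threshold_nm: float = 1.5,
                 sustained_ps: float = 100.0) -> UnboundFlag:
    """Discard when any monitored distance exceeds ``threshold_nm``
    continuously for at least ``sustained_ps``; brief excursions are kept."""
    if not monitors:
        raise ValueError("need at least one monitored distance series")
    best: UnboundFlag | None = None
    for name, series in monitors.items():
        r = np.asarray(series, dtype=float).ravel()
        if r.size == 0:
            raise ValueError(f"empty monitor series {name!r}")
        above = r > threshold_nm
        edges = np.flatnonzero(np.diff(above.astype(int)) != 0)
        starts = np.concatenate([[0], edges + 1])
        ends = np.concatenate([edges + 1, [r.size]])
        for a, b in zip(starts, ends):
            if above[a] and (b - a) * dt_ps >= sustained_ps:
                onset = a * dt_ps
                if best is None or onset < (best.first_violation_ps or math.inf):
                    best = UnboundFlag(False, onset, name)
                break
    return best if best is not None else UnboundFlag(True, None, None)
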