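"""One-step-perturbation free-energy estimation.

A single simulation of a softened, achiral reference compound R visits
configurations representative of all 32 stereoisomers.  The free energy of
real compound i relative to R follows from Zwanzig's perturbation formula

    dG_{i,R} = -kBT ln < exp(-(H_i - H_R)/kBT) >_R ,

where the average runs over reference-ensemble frames and only the few
bonded terms that differ between i and R contribute to dH = H_i - H_R.
Estimates from several reference Hamiltonians are transferred to a common
reference and combined by exponential averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .sampler import Trajectory
from .stereo import (
    StereoCode,
    SugarIdentity,
    SugarTopology,
    ThermoConditions,
    code_to_identity,
    perturbation_terms,
    _improper_energy,
    _proper_energy,
    _angle_energy,
)
from .uncertainty import autocorrelation_stats, combine_weighted_errors, \
    propagate_through_zwanzig

__all__ = [
    "PerturbationSeries",
    "FreeEnergyEstimate",
    "OccurrenceStats",
    "perturbation_energy_series",
    "zwanzig",
    "classify_frames",
    "occurrence_stats",
    "reference_transfer",
    "reweight_free_energy",
    "combine_references",
]


@dataclass
class PerturbationSeries:
    """Per-frame perturbation energies dH_{R->i} for a set of targets."""

    targets: tuple[SugarIdentity, ...]
    dH: np.ndarray  # (n_frames, n_targets), kJ/mol
    reference_level: str

    def __post_init__(self) -> None:
        if self.dH.ndim != 2 or self.dH.shape[1] != len(self.targets):
            raise ValueError("dH must be (n_frames, n_targets)")
        if not np.all(np.isfinite(self.dH)):
            raise ValueError("perturbation energies must be finite")

    def column(self, target: SugarIdentity | int) -> np.ndarray:
        if isinstance(target, SugarIdentity):
            idx = [t.index for t in self.targets].index(target.index)
        else:
            idx = [t.index for t in self.targets].index(target)
        return self.dH[:, idx]


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """OSP estimate with correlated-error bar and sampling diagnostics."""

    state: str  # sugar name or reference tag
    value: float  # kJ/mol; +inf when unsampled
    stderr: float  # kJ/mol
    n_frames: int
    max_weight: float = 0.0  # largest normalized Boltzmann weight
    unsampled: bool = False

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")

    @property
    def unreliable(self) -> bool:
        """A single frame dominating the average makes the estimate suspect."""
        return self.unsampled or self.max_weight > 0.5


def perturbation_energy_series(
    trajectory: Trajectory, reference: SugarTopology,
    targets: Sequence[SugarIdentity] | None = None,
) -> PerturbationSeries:
    """dH_{R->i} per frame, from the term pairs that differ between the
    reference and each target (all identical terms cancel exactly)."""
    if targets is None:
        from .stereo import all_identities
        targets = all_identities()
    n = trajectory.n_frames
    if trajectory.xi.shape[1] != 5:
        raise ValueError("trajectory is missing improper-angle channels xi1..xi5")
    if trajectory.phi.shape[1] != len(reference.propers):
        raise ValueError("trajectory is missing ring-torsion channels phi*")
    if trajectory.theta.shape[1] != len(reference.angles):
        raise ValueError("trajectory is missing ring-angle channels theta*")
    dH = np.zeros((n, len(targets)))
    # proper/angle differences are target-independent: compute once
    _, diffs0 = perturbation_terms(reference, targets[0])
    shared = np.zeros(n)
    for kind, rt, tt in diffs0:
        if kind == "proper":
            j = [p.label for p in reference.propers].index(rt.label)
            shared += _proper_energy(tt, trajectory.phi[:, j]) \
                - _proper_energy(rt, trajectory.phi[:, j])
        elif kind == "angle":
            j = [a.label for a in reference.angles].index(rt.label)
            shared += _angle_energy(tt, trajectory.theta[:, j]) \
                - _angle_energy(rt, trajectory.theta[:, j])
    for t, target in enumerate(targets):
        _, diffs = perturbation_terms(reference, target)
        col = shared.copy()
        for kind, rt, tt in diffs:
            if kind != "improper":
                continue
            k = ("C1", "C2", "C3", "C4", "C5").index(tt.center)
            col += _improper_energy(tt, trajectory.xi[:, k]) \
                - _improper_energy(rt, trajectory.xi[:, k])
        dH[:, t] = col
    return PerturbationSeries(tuple(targets), dH, reference.reference_level)


def zwanzig(dH: np.ndarray, conditions: ThermoConditions,
            state: str = "", with_stderr: bool = True) -> FreeEnergyEstimate:
    """Exponential (Zwanzig) free-energy average of a dH series.

    Log-sum-exp shifting guards against overflow for |dH| up to 1e4 kJ/mol.
    Frames with dH = +inf carry zero weight; if every frame does, the state
    is reported unsampled with dG = +inf.
    """
    x = np.asarray(dH, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty perturbation-energy series")
    if np.any(np.isnan(x)) or np.any(x == -np.inf):
        raise ValueError("dH must not contain NaN or -inf")
    kBT = conditions.kBT
    n = x.size
    finite = np.isfinite(x)
    if not finite.any():
        return FreeEnergyEstimate(state, math.inf, 0.0, n, 0.0, unsampled=True)
    log_w = -x / kBT  # -inf where dH = +inf
    log_mean = logsumexp(log_w) - math.log(n)
    value = -kBT * log_mean
    max_weight = float(np.exp(log_w.max() - logsumexp(log_w)))
    stderr = 0.0
    if with_stderr and n >= 10:
        w = np.exp(log_w - log_w[finite].max())
        w[~finite] = 0.0
        stats = autocorrelation_stats(w)
        if stats.mean > 0:
            stderr = propagate_through_zwanzig(stats, conditions)
    return FreeEnergyEstimate(state, float(value), stderr, n, max_weight)


def classify_frames(trajectory: Trajectory) -> np.ndarray:
    """Per-frame stereoisomer index 1..32 from the signs of xi1..xi5.

    Digit 2 when xi >= 0, digit 4 when xi < 0 (xi exactly 0 is a
    measure-zero tie broken deterministically toward digit 2).
    """
    if trajectory.xi.shape[1] != 5:
        raise ValueError("need xi1..xi5 to classify frames")
    bits = (trajectory.xi < 0).astype(int)  # 1 where digit is 4
    weights = np.array([4, 1, 8, 2, 16])
    return 1 + bits @ weights


@dataclass(frozen=True)
class OccurrenceStats:
    """Per-state sampling statistics of a classified trajectory."""

    time_fraction: np.ndarray  # (32,), sums to 1
    qualifying_runs: np.ndarray  # (32,), runs with lifetime >= threshold
    min_lifetime_ps: float


def occurrence_stats(states: np.ndarray, dt_ps: float,
                     min_lifetime_ps: float = 1.0) -> OccurrenceStats:
    """Run-length statistics: per-state time fractions and the count of
    contiguous visits lasting at least ``min_lifetime_ps``."""
    s = np.asarray(states, dtype=int).ravel()
    if s.size == 0:
        raise ValueError("empty state series")
    if s.min() < 1 or s.max() > 32:
        raise ValueError("state indices must be in 1..32")
    frac = np.bincount(s, minlength=33)[1:] / s.size
    boundaries = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [s.size]])
    runs = np.zeros(32, dtype=int)
    for a, b in zip(starts, ends):
        if (b - a) * dt_ps >= min_lifetime_ps:
            runs[s[a] - 1] += 1
    return OccurrenceStats(frac, runs, min_lifetime_ps)


def _hamiltonian_difference(trajectory: Trajectory, h_from: SugarTopology,
                            h_to: SugarTopology) -> np.ndarray:
    """Per-frame H_to - H_from over the shared coordinate channels."""
    from .stereo import bonded_energy
    e_to = bonded_energy(h_to, trajectory.xi, trajectory.phi, trajectory.theta)
    e_from = bonded_energy(h_from, trajectory.xi, trajectory.phi, trajectory.theta)
    return np.atleast_1d(e_to - e_from)


def reference_transfer(trajectory: Trajectory, r2: SugarTopology,
                       r1: SugarTopology, conditions: ThermoConditions,
                       min_effective_frames: float = 10.0) -> FreeEnergyEstimate:
    """dG_{R2->R1} from R2's frames: -kBT ln < exp(-(H_R1-H_R2)/kBT) >_R2.

    Flags the estimate unsampled when the effective sample size of the
    transfer weights falls below ``min_effective_frames`` (negligible
    overlap must not be returned silently).
    """
    dH = _hamiltonian_difference(trajectory, r2, r1)
    est = zwanzig(dH, conditions, state=f"{r2.reference_level}->{r1.reference_level}")
    w = np.exp(-(dH - dH.min()) / conditions.kBT)
    ess = w.sum() ** 2 / (w ** 2).sum()
    if ess < min_effective_frames:
        est = FreeEnergyEstimate(est.state, est.value, est.stderr,
                                 est.n_frames, est.max_weight, unsampled=True)
    return est


def reweight_free_energy(trajectory: Trajectory, r2: SugarTopology,
                         r1: SugarTopology, target: SugarIdentity,
                         conditions: ThermoConditions) -> FreeEnergyEstimate:
    """dG_{R1->i} evaluated from a simulation of R2.

    Frame-algebraically dG_{R1->i} = dG_{R2->i} - dG_{R2->R1}; both terms
    use the same R2 frames, so the identity holds exactly (telescoping of
    identical weights), not just in expectation.
    """
    series = perturbation_energy_series(trajectory, r2, [target])
    d_to_i = zwanzig(series.dH[:, 0], conditions, state=target.name)
    d_to_r1 = reference_transfer(trajectory, r2, r1, conditions)
    value = d_to_i.value - d_to_r1.value
    stderr = math.hypot(d_to_i.stderr, d_to_r1.stderr)
    return FreeEnergyEstimate(target.name, value, stderr, trajectory.n_frames,
                              max(d_to_i.max_weight, d_to_r1.max_weight),
                              unsampled=d_to_i.unsampled or d_to_r1.unsampled)


def combine_references(estimates: Sequence[FreeEnergyEstimate],
                       conditions: ThermoConditions) -> FreeEnergyEstimate:
    """Exponential average of estimates sharing a common reference:

        dG = -kBT ln( (1/m) sum_i exp(-dG_i/kBT) ).

    The arithmetic mean inside the logarithm makes the combination of equal
    values the identity; unsampled inputs (dG = +inf) contribute zero
    weight, and the combined error is the Boltzmann-weighted mean of the
    individual errors.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    kBT = conditions.kBT
    vals = np.array([e.value for e in estimates], dtype=float)
    errs = np.array([e.stderr for e in estimates], dtype=float)
    usable = np.isfinite(vals)
    if not usable.any():
        return FreeEnergyEstimate(estimates[0].state, math.inf, 0.0,
                                  sum(e.n_frames for e in estimates),
                                  0.0, unsampled=True)
    shift = vals[usable].min()
    w = np.where(usable, np.exp(-(vals - shift) / kBT), 0.0)
    value = shift - kBT * math.log(w.sum() / len(vals))
    stderr = combine_weighted_errors(errs[usable], w[usable])
    return FreeEnergyEstimate(
        estimates[0].state, float(value), float(stderr),
        sum(e.n_frames for e in estimates),
        max(e.max_weight for e in estimates),
    )
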