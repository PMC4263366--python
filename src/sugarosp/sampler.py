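"""Synthetic trajectory generation with exact ground truth.

A Metropolis Monte Carlo sampler over the internal coordinates
(xi_1..xi_5, ring torsions phi, ring angles theta) stands in for the
explicit-solvent molecular dynamics that would produce these series in
production.  The toy Hamiltonian is the bonded energy of the (softened)
topology plus, per stereocenter, a quartic double-well confining term with
minima at +/-35.264 deg — the role the molecular environment plays for the
real reference compound — plus optional per-center bias energies that mimic
a chiral binding site.  Because the default Hamiltonian is separable per
coordinate, every ground truth (state free energies, well populations,
reactive fractions) is available from 1-D quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stereo import (
    SugarIdentity,
    SugarTopology,
    ThermoConditions,
    XI0_MAGNITUDE,
    bonded_energy,
    perturbation_terms,
    real_topology,
    _improper_energy,
    _proper_energy,
    _angle_energy,
)

__all__ = [
    "DistanceModel",
    "ToyEnvironment",
    "Trajectory",
    "DiscreteToySystem",
    "run_sampler",
    "exact_state_free_energies",
    "exact_well_population",
    "make_ar1_series",
    "synthesize_probe_distances",
]


@dataclass(frozen=True)
class DistanceModel:
    """Probe-distance surrogate: d = baseline + offset * 1[xi > 0] + noise.

    One (baseline, offset) pair per probe site HC1..HC4, in nm.  The
    indicator ties the distance to the chirality of the corresponding
    stereocenter so that reactive fractions have closed-form ground truth.
    """

    baseline: tuple[float, float, float, float] = (0.28, 0.28, 0.35, 0.35)
    offset: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    sigma: float = 0.0  # Gaussian noise, nm

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class ToyEnvironment:
    """Surrogate environment of the toy sampler.

    ``bias`` adds b_k (kJ/mol) to the xi_k > 0 well — zero in achiral
    environments (vacuum, water bath), nonzero to emulate a chiral binding
    site.  ``coupling`` optionally couples the signs of neighbouring
    stereocenters; the quadrature oracle requires coupling = 0.
    """

    kind: str = "achiral_bath"  # vacuum | achiral_bath | chiral_site
    bias: tuple[float, float, float, float, float] = (0.0,) * 5
    coupling: float = 0.0  # kJ/mol
    barrier: float = 5.0  # double-well barrier height, kJ/mol (~2 kBT at 300 K)
    distance_model: DistanceModel | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("vacuum", "achiral_bath", "chiral_site"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind != "chiral_site" and any(b != 0.0 for b in self.bias):
            raise ValueError("achiral environments must have zero bias energies")


@dataclass
class Trajectory:
    """Ordered frames of internal coordinates, stored every ``dt_ps`` ps."""

    xi: np.ndarray  # (n, 5) degrees
    phi: np.ndarray  # (n, 6) degrees
    theta: np.ndarray  # (n, 6) degrees
    dt_ps: float = 0.5
    environment: ToyEnvironment | None = None
    reference_level: str = "ab"
    seed: int | None = None
    distances: np.ndarray | None = None  # (n, 4) nm, probe sites HC1..HC4
    acceptance: float | None = None

    def __post_init__(self) -> None:
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if len(self.xi) == 0:
            raise ValueError("trajectory must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.xi.shape[0]


def _double_well(xi: np.ndarray, barrier: float,
                 xi0: float = XI0_MAGNITUDE) -> np.ndarray:
    """Quartic confinement: 0 at +/-xi0, ``barrier`` at 0, growing outside."""
    s = (np.asarray(xi, dtype=float) / xi0) ** 2
    return barrier * (s - 1.0) ** 2


def _xi_energy(topology: SugarTopology, environment: ToyEnvironment,
               xi: np.ndarray, k: int) -> np.ndarray:
    """Per-center xi Hamiltonian (no coupling term)."""
    e = _double_well(xi, environment.barrier)
    e = e + _improper_energy(topology.impropers[k], xi)
    if environment.bias[k] != 0.0:
        e = e + environment.bias[k] * (np.asarray(xi) > 0)
    return e


def run_sampler(topology: SugarTopology, environment: ToyEnvironment,
                n_steps: int, seed: int,
                conditions: ThermoConditions = ThermoConditions()) -> Trajectory:
    """Metropolis Monte Carlo over (xi, phi, theta); one sweep per frame.

    Proposal widths are auto-tuned toward 30-50% acceptance during a burn-in
    of 5% of ``n_steps`` (discarded).  Deterministic given ``seed``.  With
    zero coupling the coordinates are independent and updated in parallel;
    with coupling the xi block is updated sequentially within each sweep.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    kBT = conditions.kBT
    n_xi, n_phi, n_theta = 5, len(topology.propers), len(topology.angles)
    nc = n_xi + n_phi + n_theta

    # start near the parent-compound minimum
    x = np.concatenate([
        np.full(n_xi, XI0_MAGNITUDE),
        np.full(n_phi, 60.0),  # torsion minimum of the m=3, cos-delta=+1 form
        np.full(n_theta, 109.5),
    ])
    widths = np.concatenate([
        np.full(n_xi, 25.0), np.full(n_phi, 40.0), np.full(n_theta, 8.0)
    ])

    # vectorized per-coordinate parameters
    imp_active = np.array([t.active for t in topology.impropers])
    imp_xi0 = np.array([t.xi0 for t in topology.impropers])
    imp_k = np.array([t.k_xi for t in topology.impropers])
    bias = np.asarray(environment.bias, dtype=float)
    k_phi = np.array([t.k_phi for t in topology.propers])
    phase = np.array([t.phase_cos for t in topology.propers], dtype=float)
    mult = np.array([t.multiplicity for t in topology.propers], dtype=float)
    k_th = np.array([t.k_theta for t in topology.angles])
    cos_th0 = np.cos(np.deg2rad([t.theta0 for t in topology.angles]))

    def coord_energy(vec: np.ndarray) -> np.ndarray:
        """Per-coordinate energies (valid without coupling)."""
        e = np.empty(nc)
        xi = vec[:n_xi]
        e[:n_xi] = _double_well(xi, environment.barrier)
        e[:n_xi] += np.where(imp_active, 0.5 * imp_k * (xi - imp_xi0) ** 2, 0.0)
        e[:n_xi] += bias * (xi > 0)
        ph = np.deg2rad(vec[n_xi:n_xi + n_phi])
        e[n_xi:n_xi + n_phi] = k_phi * (1.0 + phase * np.cos(mult * ph))
        th = np.deg2rad(vec[n_xi + n_phi:])
        e[n_xi + n_phi:] = 0.5 * k_th * (np.cos(th) - cos_th0) ** 2
        return e

    def coupling_energy(xi_vec: np.ndarray) -> float:
        if environment.coupling == 0.0:
            return 0.0
        s = xi_vec / XI0_MAGNITUDE
        return environment.coupling * float(np.sum(s[:-1] * s[1:]))

    separable = environment.coupling == 0.0
    burn = max(1, int(0.05 * n_steps))
    xi_out = np.empty((n_steps, n_xi))
    phi_out = np.empty((n_steps, n_phi))
    theta_out = np.empty((n_steps, n_theta))
    accepted = np.zeros(nc)
    attempted = np.zeros(nc)
    e_coord = coord_energy(x)

    tune_window = max(50, burn // 10)
    for sweep in range(burn + n_steps):
        if separable:
            prop = x + rng.normal(0.0, widths, nc)
            # wrap torsions into (-180, 180]
            prop[n_xi:n_xi + n_phi] = (
                (prop[n_xi:n_xi + n_phi] + 180.0) % 360.0 - 180.0)
            e_prop = coord_energy(prop)
            # reject theta proposals outside (0, 180)
            th = prop[n_xi + n_phi:]
            invalid_theta = (th <= 0.0) | (th >= 180.0)
            de = e_prop - e_coord
            acc = rng.random(nc) < np.exp(np.clip(-de / kBT, -700, 0))
            acc[n_xi + n_phi:] &= ~invalid_theta
            x = np.where(acc, prop, x)
            e_coord = np.where(acc, e_prop, e_coord)
            accepted += acc
            attempted += 1
        else:
            for c in range(nc):
                xp = x.copy()
                xp[c] += rng.normal(0.0, widths[c])
                if n_xi <= c < n_xi + n_phi:
                    xp[c] = (xp[c] + 180.0) % 360.0 - 180.0
                if c >= n_xi + n_phi and not 0.0 < xp[c] < 180.0:
                    attempted[c] += 1
                    continue
                e_new = coord_energy(xp)[c]
                de = e_new - e_coord[c]
                if c < n_xi:
                    de += coupling_energy(xp[:n_xi]) - coupling_energy(x[:n_xi])
                attempted[c] += 1
                if rng.random() < np.exp(min(0.0, -de / kBT)):
                    x = xp
                    e_coord[c] = e_new
                    accepted[c] += 1
        if sweep < burn:
            if (sweep + 1) % tune_window == 0:
                rate = accepted / np.maximum(attempted, 1)
                widths *= np.clip(rate / 0.4, 0.5, 2.0)
                widths = np.clip(widths, 1e-3, 170.0)
                accepted[:] = 0
                attempted[:] = 0
            if sweep == burn - 1:
                accepted[:] = 0
                attempted[:] = 0
        else:
            i = sweep - burn
            xi_out[i] = x[:n_xi]
            phi_out[i] = x[n_xi:n_xi + n_phi]
            theta_out[i] = x[n_xi + n_phi:]

    rate = float(accepted.sum() / max(attempted.sum(), 1))
    if rate == 0.0:
        warnings.warn(
            "zero Metropolis acceptance over the production window; "
            "reduce proposal widths or check the Hamiltonian scale",
            RuntimeWarning,
        )
    return Trajectory(
        xi=xi_out, phi=phi_out, theta=theta_out,
        environment=environment, reference_level=topology.reference_level,
        seed=seed, acceptance=rate,
    )


# ---------------------------------------------------------------------------
# Quadrature oracles (exact up to grid resolution; separable Hamiltonians only)

_XI_GRID = np.linspace(-150.0, 150.0, 6001)
_PHI_GRID = np.linspace(-180.0, 180.0, 3601)
_THETA_GRID = np.linspace(0.5, 179.5, 3581)


def _log_partition(energy: np.ndarray, grid: np.ndarray, kBT: float) -> float:
    w = np.exp(-(energy - energy.min()) / kBT)
    return float(np.log(np.trapezoid(w, grid)) - energy.min() / kBT)


def exact_state_free_energies(
    topology: SugarTopology, environment: ToyEnvironment,
    targets: Sequence[SugarIdentity],
    conditions: ThermoConditions = ThermoConditions(),
) -> np.ndarray:
    """Quadrature free energies dG(reference -> target), kJ/mol.

    Valid only for separable Hamiltonians (coupling = 0); the per-center,
    per-torsion and per-angle partition integrals factorize, so each dG is a
    sum of 1-D log-partition differences.  Grid resolution keeps the error
    below 0.01 kJ/mol.
    """
    if environment.coupling != 0.0:
        raise ValueError("quadrature oracle requires zero coupling (separable)")
    kBT = conditions.kBT
    log_z_ref = 0.0
    for k in range(5):
        e = _xi_energy(topology, environment, _XI_GRID, k)
        log_z_ref += _log_partition(e, _XI_GRID, kBT)
    for term in topology.propers:
        log_z_ref += _log_partition(_proper_energy(term, _PHI_GRID), _PHI_GRID, kBT)
    for term in topology.angles:
        log_z_ref += _log_partition(_angle_energy(term, _THETA_GRID), _THETA_GRID, kBT)

    k_xi = topology.impropers[0].k_xi
    xi0_mag = abs(topology.impropers[0].xi0) or XI0_MAGNITUDE
    out = np.empty(len(targets))
    for t, target in enumerate(targets):
        tgt = real_topology(target, k_xi=k_xi, xi0_mag=xi0_mag)
        log_z = 0.0
        for k in range(5):
            e = _xi_energy(tgt, environment, _XI_GRID, k)
            log_z += _log_partition(e, _XI_GRID, kBT)
        for term in tgt.propers:
            log_z += _log_partition(_proper_energy(term, _PHI_GRID), _PHI_GRID, kBT)
        for term in tgt.angles:
            log_z += _log_partition(_angle_energy(term, _THETA_GRID), _THETA_GRID, kBT)
        out[t] = -kBT * (log_z - log_z_ref)
    return out


def exact_well_population(topology: SugarTopology, environment: ToyEnvironment,
                          center: int,
                          conditions: ThermoConditions = ThermoConditions()) -> float:
    """Quadrature probability of xi_center > 0 under the toy Hamiltonian."""
    kBT = conditions.kBT
    e = _xi_energy(topology, environment, _XI_GRID, center)
    w = np.exp(-(e - e.min()) / kBT)
    pos = _XI_GRID >= 0  # inclusive: [0, max] is exactly half a symmetric grid
    return float(np.trapezoid(w[pos], _XI_GRID[pos]) / np.trapezoid(w, _XI_GRID))


@dataclass(frozen=True)
class DiscreteToySystem:
    """Finite-state system used as a brute-force oracle for estimators."""

    energies: tuple[float, ...]  # kJ/mol
    kBT: float

    def __post_init__(self) -> None:
        if len(self.energies) < 2:
            raise ValueError("need at least 2 states")
        if not all(np.isfinite(self.energies)):
            raise ValueError("state energies must be finite")

    def populations(self) -> np.ndarray:
        e = np.asarray(self.energies)
        w = np.exp(-(e - e.min()) / self.kBT)
        return w / w.sum()

    def free_energy(self) -> float:
        """-kBT ln Z (kJ/mol), by direct summation."""
        e = np.asarray(self.energies)
        shift = e.min()
        return float(shift - self.kBT * np.log(np.exp(-(e - shift) / self.kBT).sum()))

    def sample(self, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.choice(len(self.energies), size=n, p=self.populations())


def make_ar1_series(mean: float, variance: float, phi: float, n: int,
                    seed: int) -> np.ndarray:
    """Stationary AR(1) series with given mean, marginal variance, lag-1
    autocorrelation ``phi``."""
    if not abs(phi) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    if variance == 0.0:
        return np.full(n, float(mean))
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(variance))
    innov_sd = np.sqrt(variance * (1.0 - phi ** 2))
    eps = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x + mean


def synthesize_probe_distances(trajectory: Trajectory,
                               environment: ToyEnvironment | None = None,
                               seed: int | None = None) -> Trajectory:
    """Fill probe distances d_HC1..d_HC4 from the distance surrogate.

    Site x follows stereocenter x: d = baseline_x + offset_x * 1[xi_x > 0]
    + Gaussian noise, truncated below at 0.05 nm.
    """
    env = environment or trajectory.environment
    if env is None or env.distance_model is None:
        raise ValueError("environment with a distance model is required")
    dm = env.distance_model
    rng = np.random.default_rng(
        seed if seed is not None else (trajectory.seed or 0) + 7919)
    n = trajectory.n_frames
    d = np.empty((n, 4))
    for x in range(4):
        d[:, x] = dm.baseline[x] + dm.offset[x] * (trajectory.xi[:, x] > 0)
    if dm.sigma > 0:
        d += rng.normal(0.0, dm.sigma, size=d.shape)
    from dataclasses import replace as _replace
    return _replace(trajectory, environment=env, distances=np.maximum(d, 0.05))
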