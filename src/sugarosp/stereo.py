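"""Stereoisomer encoding and the bonded-term energy model.

The 32 aldohexopyranoses are indexed by a 5-digit chirality code, one digit
per ring stereocenter C1..C5.  In a united-atom force field the hydrogen at
each CH stereocenter is implicit and chirality is enforced by a harmonic
improper-dihedral term; digit 2 denotes the improper target angle
+35.264 deg and digit 4 its mirror image -35.264 deg.  beta-D-glucose is the
all-2 parent compound.  Softened reference Hamiltonians are derived from it
by (a) deactivating the five impropers, (ab) additionally lowering six
ring-torsion force constants and (abc) additionally lowering six ring
bond-angle force constants, so that a single simulation of the reference
visits configurations representative of every stereoisomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KB",
    "XI0_MAGNITUDE",
    "K_XI_DEFAULT",
    "StereoCode",
    "SugarIdentity",
    "ImproperTerm",
    "ProperTerm",
    "AngleTerm",
    "SugarTopology",
    "ThermoConditions",
    "code_to_identity",
    "identity_from_index",
    "all_identities",
    "enantiomer_of",
    "real_topology",
    "reference_topology",
    "bonded_energy",
    "perturbation_terms",
    "write_topology",
    "read_topology",
    "load_stereocode_table",
]

#: Boltzmann constant in kJ mol^-1 K^-1.
KB = 0.008314462

#: Magnitude of the improper-dihedral target angle at a tetrahedral
#: united-atom stereocenter, degrees.
XI0_MAGNITUDE = 35.264

#: Improper force constant, kJ mol^-1 deg^-2.
K_XI_DEFAULT = 0.102

_CENTERS = ("C1", "C2", "C3", "C4", "C5")

# Base-name pattern over digits at positions (C2, C3, C4); C1 sets the
# anomer (2 = beta, 4 = alpha) and C5 the series (2 = d, 4 = l).
_BASE_NAMES = {
    (2, 2, 2): "glucose",
    (4, 2, 2): "mannose",
    (2, 2, 4): "galactose",
    (4, 2, 4): "talose",
    (2, 4, 2): "allose",
    (4, 4, 2): "altrose",
    (2, 4, 4): "gulose",
    (4, 4, 4): "idose",
}


class StereoCodeError(ValueError):
    """Raised for malformed 5-digit chirality codes."""


@dataclass(frozen=True, order=True)
class StereoCode:
    """5-digit chirality code, one digit in {2, 4} per center C1..C5."""

    digits: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.digits) != 5 or any(d not in (2, 4) for d in self.digits):
            raise StereoCodeError(
                f"chirality code must be 5 digits over {{2,4}}, got {self.digits!r}"
            )

    @classmethod
    def from_string(cls, s: str) -> "StereoCode":
        if len(s) != 5 or any(ch not in "24" for ch in s):
            raise StereoCodeError(f"malformed chirality code {s!r}")
        return cls(tuple(int(ch) for ch in s))  # type: ignore[arg-type]

    def __str__(self) -> str:
        return "".join(str(d) for d in self.digits)

    def __format__(self, spec: str) -> str:
        return format(str(self), spec)

    def swapped(self) -> "StereoCode":
        """Mirror-image code: 2 <-> 4 at every position."""
        return StereoCode(tuple(6 - d for d in self.digits))  # type: ignore[arg-type]

    @property
    def index(self) -> int:
        """1-based table index; the bit weights reproduce the published order."""
        b = [1 if d == 4 else 0 for d in self.digits]
        return 1 + 4 * b[0] + b[1] + 8 * b[2] + 2 * b[3] + 16 * b[4]


@dataclass(frozen=True)
class SugarIdentity:
    """One of the 32 aldohexopyranoses, as named in the published lookup."""

    code: StereoCode
    index: int
    anomer: str  # "alpha" | "beta"
    series: str  # "d" | "l"
    base_name: str

    @property
    def name(self) -> str:
        return f"{self.anomer}-{self.series}-{self.base_name}"

    def __str__(self) -> str:
        return self.name


def code_to_identity(code: StereoCode | str | Sequence[int]) -> SugarIdentity:
    """Map a 5-digit chirality code to its sugar identity.

    Total over all 32 valid codes; raises :class:`StereoCodeError` otherwise.
    """
    if isinstance(code, str):
        code = StereoCode.from_string(code)
    elif not isinstance(code, StereoCode):
        code = StereoCode(tuple(code))  # type: ignore[arg-type]
    d = code.digits
    return SugarIdentity(
        code=code,
        index=code.index,
        anomer="beta" if d[0] == 2 else "alpha",
        series="d" if d[4] == 2 else "l",
        base_name=_BASE_NAMES[(d[1], d[2], d[3])],
    )


def identity_from_index(index: int) -> SugarIdentity:
    """Inverse of the index <-> code bijection (index in 1..32)."""
    if not 1 <= index <= 32:
        raise StereoCodeError(f"sugar index must be in 1..32, got {index}")
    x = index - 1
    bits = ((x >> 2) & 1, x & 1, (x >> 3) & 1, (x >> 1) & 1, (x >> 4) & 1)
    return code_to_identity(tuple(4 if b else 2 for b in bits))


def all_identities() -> list[SugarIdentity]:
    """All 32 identities in table order."""
    return [identity_from_index(i) for i in range(1, 33)]


def enantiomer_of(identity: SugarIdentity) -> SugarIdentity:
    """Mirror-image stereoisomer: digit-swapped code, index 33 - i."""
    return code_to_identity(identity.code.swapped())


def load_stereocode_table() -> pd.DataFrame:
    """Packaged code <-> name lookup (authoritative fixture)."""
    with resources.files("sugarosp.data").joinpath("stereocodes.csv").open() as fh:
        return pd.read_csv(fh, dtype={"code": str})


# ---------------------------------------------------------------------------
# Bonded terms


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic improper dihedral V = 1/2 k_xi (xi - xi0)^2 at a stereocenter."""

    center: str
    type_code: int  # 2 -> xi0 = +XI0, 4 -> xi0 = -XI0
    xi0: float  # degrees
    k_xi: float  # kJ mol^-1 deg^-2
    active: bool = True


@dataclass(frozen=True)
class ProperTerm:
    """Cosine torsion V = k_phi (1 + phase_cos * cos(m phi))."""

    label: str
    multiplicity: int
    phase_cos: int  # +1 or -1
    k_phi: float  # kJ mol^-1

    def __post_init__(self) -> None:
        if self.k_phi < 0:
            raise ValueError(f"k_phi must be >= 0, got {self.k_phi}")


@dataclass(frozen=True)
class AngleTerm:
    """Cosine-harmonic bond angle V = 1/2 k_theta (cos(theta) - cos(theta0))^2."""

    label: str
    theta0: float  # degrees
    k_theta: float  # kJ mol^-1

    def __post_init__(self) -> None:
        if self.k_theta < 0:
            raise ValueError(f"k_theta must be >= 0, got {self.k_theta}")
        if not 0.0 < self.theta0 < 180.0:
            raise ValueError(f"theta0 must be in (0, 180), got {self.theta0}")


# Ring torsions of the pyranose ring with their full and softened force
# constants (kJ/mol).  The softened values define the ab/abc reference levels.
_PROPER_SPECS = (
    ("O5-C1-C2-C3", 2.09, 0.418),
    ("C5-O5-C1-C2", 2.09, 0.418),
    ("C1-C2-C3-C4", 5.92, 1.05),
    ("C2-C3-C4-C5", 5.92, 1.05),
    ("C3-C4-C5-O5", 3.77, 1.05),
    ("C4-C5-O5-C1", 3.77, 1.05),
)

# Ring bond angles; the ether angle at O5 carries the stiffer constant.
_ANGLE_SPECS = (
    ("C5-O5-C1", 380.0, 285.0),
    ("O5-C1-C2", 320.0, 285.0),
    ("C1-C2-C3", 320.0, 285.0),
    ("C2-C3-C4", 320.0, 285.0),
    ("C3-C4-C5", 320.0, 285.0),
    ("C4-C5-O5", 320.0, 285.0),
)

_TETRAHEDRAL = 109.5  # degrees, ring-angle reference

REFERENCE_LEVELS = ("real", "a", "ab", "abc")


@dataclass(frozen=True)
class SugarTopology:
    """Bonded-term set of a sugar or softened reference Hamiltonian.

    Only the terms that can differ between the reference and a real
    stereoisomer are represented; nonbonded and bond-stretch terms are out
    of scope of the perturbation and omitted.
    """

    impropers: tuple[ImproperTerm, ...]
    propers: tuple[ProperTerm, ...]
    angles: tuple[AngleTerm, ...]
    reference_level: str = "real"

    def __post_init__(self) -> None:
        if self.reference_level not in REFERENCE_LEVELS:
            raise ValueError(f"unknown reference level {self.reference_level!r}")
        if len(self.impropers) != 5:
            raise ValueError("a sugar topology carries exactly 5 improper terms")


def _impropers_for(code: StereoCode, k_xi: float, xi0_mag: float,
                   active: bool) -> tuple[ImproperTerm, ...]:
    return tuple(
        ImproperTerm(
            center=_CENTERS[k],
            type_code=d,
            xi0=xi0_mag if d == 2 else -xi0_mag,
            k_xi=k_xi,
            active=active,
        )
        for k, d in enumerate(code.digits)
    )


def _full_propers() -> tuple[ProperTerm, ...]:
    return tuple(ProperTerm(lbl, 3, 1, k) for lbl, k, _ in _PROPER_SPECS)


def _full_angles() -> tuple[AngleTerm, ...]:
    return tuple(AngleTerm(lbl, _TETRAHEDRAL, k) for lbl, k, _ in _ANGLE_SPECS)


def real_topology(identity: SugarIdentity, k_xi: float = K_XI_DEFAULT,
                  xi0_mag: float = XI0_MAGNITUDE) -> SugarTopology:
    """Physical bonded topology of one stereoisomer (impropers active)."""
    return SugarTopology(
        impropers=_impropers_for(identity.code, k_xi, xi0_mag, active=True),
        propers=_full_propers(),
        angles=_full_angles(),
        reference_level="real",
    )


def reference_topology(level: str, k_xi: float = K_XI_DEFAULT,
                       xi0_mag: float = XI0_MAGNITUDE) -> SugarTopology:
    """Softened reference Hamiltonian at level 'a', 'ab' or 'abc'.

    a:   the five stereocenter impropers are deactivated;
    ab:  additionally the six ring-torsion constants are lowered;
    abc: additionally the six ring-angle constants are lowered.
    """
    if level not in ("a", "ab", "abc"):
        raise ValueError(f"reference level must be a/ab/abc, got {level!r}")
    parent = code_to_identity("22222")  # beta-d-glucose parent
    impropers = _impropers_for(parent.code, k_xi, xi0_mag, active=False)
    if level in ("ab", "abc"):
        propers = tuple(ProperTerm(lbl, 3, 1, low) for lbl, _, low in _PROPER_SPECS)
    else:
        propers = _full_propers()
    if level == "abc":
        angles = tuple(AngleTerm(lbl, _TETRAHEDRAL, low) for lbl, _, low in _ANGLE_SPECS)
    else:
        angles = _full_angles()
    return SugarTopology(impropers, propers, angles, reference_level=level)


def _improper_energy(term: ImproperTerm, xi: np.ndarray) -> np.ndarray:
    if not term.active:
        return np.zeros_like(np.asarray(xi, dtype=float))
    return 0.5 * term.k_xi * (np.asarray(xi, dtype=float) - term.xi0) ** 2


def _proper_energy(term: ProperTerm, phi_deg: np.ndarray) -> np.ndarray:
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return term.k_phi * (1.0 + term.phase_cos * np.cos(term.multiplicity * phi))


def _angle_energy(term: AngleTerm, theta_deg: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    theta0 = math.radians(term.theta0)
    return 0.5 * term.k_theta * (np.cos(theta) - math.cos(theta0)) ** 2


def bonded_energy(topology: SugarTopology, xi: Sequence[float],
                  phi: Sequence[float], theta: Sequence[float]) -> float | np.ndarray:
    """Total bonded energy (kJ/mol) of active terms at the given coordinates.

    ``xi`` carries the 5 improper angles, ``phi`` the ring torsions and
    ``theta`` the ring bond angles, all in degrees.  Each may be a 1-D
    per-term vector (one frame) or a 2-D (n_frames, n_terms) array.
    """
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if xi.shape[1] != len(topology.impropers):
        raise ValueError(
            f"expected {len(topology.impropers)} improper angles, got {xi.shape[1]}"
        )
    if phi.shape[1] != len(topology.propers):
        raise ValueError(
            f"expected {len(topology.propers)} ring torsions, got {phi.shape[1]}"
        )
    if theta.shape[1] != len(topology.angles):
        raise ValueError(
            f"expected {len(topology.angles)} ring angles, got {theta.shape[1]}"
        )
    e = np.zeros(xi.shape[0])
    for k, term in enumerate(topology.impropers):
        e += _improper_energy(term, xi[:, k])
    for j, term in enumerate(topology.propers):
        e += _proper_energy(term, phi[:, j])
    for j, term in enumerate(topology.angles):
        e += _angle_energy(term, theta[:, j])
    return float(e[0]) if e.shape == (1,) else e


def perturbation_terms(
    reference: SugarTopology, target: SugarIdentity
) -> tuple[SugarTopology, list[tuple[str, object, object]]]:
    """Real-compound topology for ``target`` plus the term pairs that differ
    from the softened reference.

    Returns ``(target_topology, diffs)`` where each diff is a
    ``(kind, reference_term, target_term)`` triple.  Only these pairs need
    re-evaluation to obtain the perturbation energy of a frame.
    """
    if reference.reference_level not in ("a", "ab", "abc"):
        raise ValueError("perturbation reference must have level a/ab/abc")
    k_xi = reference.impropers[0].k_xi
    xi0_mag = abs(reference.impropers[0].xi0)
    tgt = real_topology(target, k_xi=k_xi, xi0_mag=xi0_mag)
    diffs: list[tuple[str, object, object]] = []
    for rt, tt in zip(reference.impropers, tgt.impropers):
        if rt.active != tt.active or rt.xi0 != tt.xi0 or rt.k_xi != tt.k_xi:
            diffs.append(("improper", rt, tt))
    for rp, tp in zip(reference.propers, tgt.propers):
        if rp != tp:
            diffs.append(("proper", rp, tp))
    for ra, ta in zip(reference.angles, tgt.angles):
        if ra != ta:
            diffs.append(("angle", ra, ta))
    return tgt, diffs


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and derived thermal energy."""

    temperature: float = 300.0  # K
    k_B: float = KB

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return self.k_B * self.temperature


# ---------------------------------------------------------------------------
# Text serialization (key-value blocks)


def write_topology(topology: SugarTopology, path) -> None:
    """Serialize as structured text blocks; round-trips losslessly."""
    lines = [f"reference_level\t{topology.reference_level}", "IMPROPERS"]
    for t in topology.impropers:
        lines.append(
            f"{t.center}\t{t.type_code}\t{t.xi0!r}\t{t.k_xi!r}\t{int(t.active)}"
        )
    lines.append("PROPERS")
    for p in topology.propers:
        lines.append(f"{p.label}\t{p.multiplicity}\t{p.phase_cos}\t{p.k_phi!r}")
    lines.append("ANGLES")
    for a in topology.angles:
        lines.append(f"{a.label}\t{a.theta0!r}\t{a.k_theta!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_topology(path) -> SugarTopology:
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not raw or not raw[0].startswith("reference_level"):
        raise ValueError(f"{path}: missing reference_level header")
    level = raw[0].split("\t")[1]
    sections: dict[str, list[list[str]]] = {}
    current = None
    for ln in raw[1:]:
        if ln in ("IMPROPERS", "PROPERS", "ANGLES"):
            current = ln
            sections[current] = []
        elif current is None:
            raise ValueError(f"{path}: data before any section header")
        else:
            sections[current].append(ln.split("\t"))
    impropers = tuple(
        ImproperTerm(c, int(tc), float(x0), float(kx), bool(int(act)))
        for c, tc, x0, kx, act in sections.get("IMPROPERS", [])
    )
    propers = tuple(
        ProperTerm(lbl, int(m), int(pc), float(k))
        for lbl, m, pc, k in sections.get("PROPERS", [])
    )
    angles = tuple(
        AngleTerm(lbl, float(t0), float(k))
        for lbl, t0, k in sections.get("ANGLES", [])
    )
    return SugarTopology(impropers, propers, angles, reference_level=level)
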