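"""Derived thermodynamic tables, experiment comparisons and ring analysis.

Downstream arithmetic of the perturbation estimates: relative solvation
free energies (water minus vacuum), beta/alpha anomer differences and their
conversion to and from equilibrium pyranose ratios, relative binding free
energies and their comparison to Michaelis-constant-derived estimates
(dG = kBT ln Km), enantiomer-pair consistency reports, deviation statistics
against experiment, and Cremer-Pople classification of pyranose-ring
conformations into the 14 canonical conformers.

Temperature conventions: 300 K for simulation-derived quantities, 303.15 K
(30 C) for experimental conversions, matching the conditions the reference
measurements were taken at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stereo import SugarIdentity, ThermoConditions, all_identities, \
    enantiomer_of

__all__ = [
    "SIM_CONDITIONS",
    "EXP_CONDITIONS",
    "load_table",
    "relative_solvation",
    "anomer_delta",
    "anomer_table",
    "ratio_to_dg",
    "dg_to_ratio",
    "km_to_relative_dg",
    "exp_average_anomers",
    "binding_vs_km_table",
    "enantiomer_report",
    "free_energy_range",
    "deviation_stats",
    "RingConformation",
    "cremer_pople",
    "classify_ring_conformation",
]

SIM_CONDITIONS = ThermoConditions(temperature=300.0)
EXP_CONDITIONS = ThermoConditions(temperature=303.15)

_TABLE_FILES = {
    "solvation": "table1_solvation.csv",
    "anomers": "table2_anomers.csv",
    "binding": "table3_binding.csv",
    "km": "table4_km.csv",
    "stereocodes": "stereocodes.csv",
}


def load_table(name: str) -> pd.DataFrame:
    """Packaged reference tables (unicode minus normalized on read)."""
    if name not in _TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; one of {sorted(_TABLE_FILES)}")
    path = resources.files("sugarosp.data").joinpath(_TABLE_FILES[name])
    with path.open(encoding="utf-8") as fh:
        text = fh.read().replace("−", "-")
    from io import StringIO
    return pd.read_csv(StringIO(text), dtype={"code": str} if name != "anomers" else None)


def relative_solvation(vac: pd.DataFrame, water: pd.DataFrame) -> pd.DataFrame:
    """Row-wise ddG_solv = dG_water - dG_vac with errors in quadrature.

    Inputs carry columns (index, value, stderr); rows are matched on
    ``index``; states missing from either side are flagged.
    """
    merged = vac.merge(water, on="index", how="outer",
                       suffixes=("_vac", "_water"))
    merged["ddg_solv"] = merged["value_water"] - merged["value_vac"]
    merged["ddg_solv_err"] = np.hypot(merged["stderr_water"],
                                      merged["stderr_vac"])
    merged["flagged"] = merged[["value_vac", "value_water"]].isna().any(axis=1)
    return merged


def anomer_delta(water: pd.DataFrame, base_name: str,
                 series: str = "d") -> float:
    """dG(beta) - dG(alpha) for one sugar in water.

    ``water`` needs columns (anomer, series, base_name, value).
    """
    sel = water[(water["base_name"] == base_name) & (water["series"] == series)]
    try:
        beta = float(sel.loc[sel["anomer"] == "beta", "value"].iloc[0])
        alpha = float(sel.loc[sel["anomer"] == "alpha", "value"].iloc[0])
    except IndexError:
        raise ValueError(
            f"both anomers of {series}-{base_name} are required") from None
    return beta - alpha


def anomer_table(water: pd.DataFrame, series: str = "d",
                 experiment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-base-name anomer free-energy differences, optionally merged with
    experimental values (columns base_name, dg_beta_alpha_experiment)."""
    rows = []
    for base in water.loc[water["series"] == series, "base_name"].unique():
        rows.append({"base_name": base,
                     "dg_beta_alpha": anomer_delta(water, base, series)})
    out = pd.DataFrame(rows)
    if experiment is not None:
        out = out.merge(experiment, on="base_name", how="left")
    return out


def ratio_to_dg(beta_over_alpha: float,
                conditions: ThermoConditions = EXP_CONDITIONS) -> float:
    """dG_beta-alpha from an equilibrium beta/alpha pyranose ratio.

    A beta-majority ratio (> 1) maps to a negative free-energy difference.
    """
    if beta_over_alpha <= 0:
        raise ValueError("beta/alpha ratio must be positive")
    return -conditions.kBT * math.log(beta_over_alpha)


def dg_to_ratio(dg_beta_alpha: float,
                conditions: ThermoConditions = EXP_CONDITIONS) -> float:
    """Inverse of :func:`ratio_to_dg`."""
    return math.exp(-dg_beta_alpha / conditions.kBT)


def km_to_relative_dg(records: pd.DataFrame, reference: str,
                      conditions: ThermoConditions = EXP_CONDITIONS) -> pd.DataFrame:
    """Experimental relative binding free energies from Michaelis constants.

    ddG(sugar) = kBT ln(Km_sugar / Km_ref); the Km units cancel in the
    ratio.  ``records`` needs columns (base_name, km_mM).
    """
    if (records["km_mM"] <= 0).any():
        raise ValueError("Michaelis constants must be positive")
    ref_rows = records.loc[records["base_name"] == reference, "km_mM"]
    if ref_rows.empty:
        raise ValueError(f"reference sugar {reference!r} not in records")
    km_ref = float(ref_rows.iloc[0])
    out = records.copy()
    out["ddg_bind_exp"] = conditions.kBT * np.log(out["km_mM"] / km_ref)
    return out


def exp_average_anomers(dg_alpha: float, dg_beta: float,
                        conditions: ThermoConditions = SIM_CONDITIONS,
                        err_alpha: float = 0.0,
                        err_beta: float = 0.0) -> tuple[float, float]:
    """Boltzmann combination of the two anomers of one sugar:

        dG = -kBT ln( (exp(-dG_a/kBT) + exp(-dG_b/kBT)) / 2 ).

    Mutarotation interconverts the anomers in solution, so experimental
    binding sees their population-weighted mixture.  The 1/2 normalization
    makes equal inputs a fixed point; an infinite (unsampled) input
    contributes zero weight.  Returns (value, weighted stderr).
    """
    kBT = conditions.kBT
    vals = np.array([dg_alpha, dg_beta], dtype=float)
    errs = np.array([err_alpha, err_beta], dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("both anomer free energies are unsampled")
    shift = vals[finite].min()
    w = np.where(finite, np.exp(-(vals - shift) / kBT), 0.0)
    value = shift - kBT * math.log(w.sum() / 2.0)
    stderr = float((w * errs).sum() / w.sum())
    return float(value), stderr


def binding_vs_km_table(water: pd.DataFrame, bound: pd.DataFrame,
                        km_records: pd.DataFrame, reference: str = "glucose",
                        series: str = "d",
                        conditions: ThermoConditions = SIM_CONDITIONS) -> pd.DataFrame:
    """Simulated anomer-averaged ddG_bind per pose next to the Km-derived
    experimental column, both relative to the reference sugar.

    ``water`` and ``bound`` need columns (anomer, series, base_name, value)
    with ``bound`` additionally carrying ``pose``.  Pose A and pose B are
    reported side by side, never merged.
    """
    exp = km_to_relative_dg(km_records, reference)
    rows = []
    for base in exp["base_name"]:
        row = {"base_name": base,
               "ddg_bind_exp": float(
                   exp.loc[exp["base_name"] == base, "ddg_bind_exp"].iloc[0])}
        for pose in sorted(bound["pose"].unique()):
            sub = bound[bound["pose"] == pose]

            def avg(df: pd.DataFrame, name: str) -> float:
                sel = df[(df["base_name"] == name) & (df["series"] == series)]
                a = float(sel.loc[sel["anomer"] == "alpha", "value"].iloc[0])
                b = float(sel.loc[sel["anomer"] == "beta", "value"].iloc[0])
                return exp_average_anomers(a, b, conditions)[0]

            ddg = (avg(sub, base) - avg(water, base)) \
                - (avg(sub, reference) - avg(water, reference))
            row[f"ddg_bind_pose{pose}"] = ddg
        rows.append(row)
    return pd.DataFrame(rows)


def enantiomer_report(values: pd.DataFrame) -> pd.DataFrame:
    """Per-pair |dG_i - dG_(33-i)| for the 16 enantiomer pairs.

    ``values`` needs columns (index, value).  Pairs with a missing member
    are reported with NaN difference.  In achiral environments the
    differences should vanish to within statistical noise; a chiral binding
    site breaks the symmetry.
    """
    v = values.set_index("index")["value"]
    rows = []
    for i in range(1, 17):
        j = 33 - i
        a = v.get(i, np.nan)
        b = v.get(j, np.nan)
        rows.append({"index_low": i, "index_high": j,
                     "abs_difference": abs(a - b)})
    return pd.DataFrame(rows)


def free_energy_range(values, exclude_max: bool = False) -> float:
    """Spread max - min of a free-energy column, optionally after dropping
    the single largest value (used to probe outlier sensitivity)."""
    v = np.sort(np.asarray(values, dtype=float))
    if exclude_max:
        v = v[:-1]
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(v[-1] - v[0])


@dataclass(frozen=True)
class DeviationStats:
    mean_signed: float
    sd: float
    max_abs: float
    min_abs: float
    mean_abs: float
    n: int


def deviation_stats(simulated, experimental) -> DeviationStats:
    """Signed and absolute deviation summary of simulation vs experiment.

    The signed mean with its sample standard deviation is the headline
    statistic; the absolute-deviation mean and extremes are also reported.
    """
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.shape != exp.shape or sim.size == 0:
        raise ValueError("columns must be aligned and non-empty")
    d = sim - exp
    return DeviationStats(
        mean_signed=float(d.mean()),
        sd=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        max_abs=float(np.abs(d).max()),
        min_abs=float(np.abs(d).min()),
        mean_abs=float(np.abs(d).mean()),
        n=d.size,
    )


# ---------------------------------------------------------------------------
# Ring-conformation classification (Cremer-Pople puckering coordinates)

# Boat / twist-boat labels by 30-degree phase sector, anchored by direct
# construction of ideal geometries with the O5-C1-C2-C3-C4-C5 ordering.
_BOATS = ("3,OB", "B1,4", "2,5B", "B3,O", "1,4B", "B2,5")
_TWISTS = ("3S1", "5S1", "2SO", "1S3", "1S5", "OS2")

RING_CONFORMERS = ("4C1", "1C4") + _BOATS + _TWISTS  # the 14 canonical forms


@dataclass(frozen=True)
class RingConformation:
    label: str
    amplitude: float  # total puckering amplitude Q, same unit as input
    theta: float  # polar angle, degrees
    phi: float  # phase angle, degrees


def cremer_pople(positions) -> tuple[float, float, float]:
    """Puckering amplitude Q, polar angle theta and phase phi (degrees) of a
    six-membered ring, atoms ordered O5-C1-C2-C3-C4-C5."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (6, 3):
        raise ValueError("need six 3-D ring-atom positions")
    center = pos.mean(axis=0)
    r = pos - center
    j = np.arange(6)
    rp = (r * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    normal = np.cross(rpp, rp)  # orientation chosen so theta=0 is the 4C1 chair
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate ring geometry")
    z = r @ (normal / nn)
    amplitude = float(np.sqrt((z ** 2).sum()))
    if amplitude < 1e-9:
        raise ValueError("planar ring: puckering undefined")
    q2c = np.sqrt(2 / 6) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2s = -np.sqrt(2 / 6) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q3 = np.sqrt(1 / 6) * (z * (-1.0) ** j).sum()
    theta = math.degrees(math.acos(np.clip(q3 / amplitude, -1.0, 1.0)))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return amplitude, theta, phi


def classify_ring_conformation(positions) -> RingConformation:
    """Assign one of the 14 canonical pyranose conformers.

    theta < 45 deg -> 4C1 chair, theta > 135 deg -> 1C4 chair; otherwise the
    phase angle selects a boat (even 30-degree sector) or twist-boat (odd
    sector).
    """
    amplitude, theta, phi = cremer_pople(positions)
    if theta < 45.0:
        label = "4C1"
    elif theta > 135.0:
        label = "1C4"
    else:
        sector = int(((phi + 15.0) % 360.0) // 30.0)
        if sector % 2 == 0:
            label = _BOATS[sector // 2]
        else:
            label = _TWISTS[sector // 2]
    return RingConformation(label, amplitude, theta, phi)
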