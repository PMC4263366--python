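"""Tab-separated time-series files.

One frame per row; a ``#``-prefixed preamble carries metadata (dt_ps,
reference_level, pose, seed); the header row names the channels: ``step``,
``xi1``..``xi5`` (deg), optional ``phi*``/``theta*`` (deg), optional
``dHC1``..``dHC4`` (nm) and optional ``dH_<code>`` (kJ/mol) columns holding
precomputed perturbation energies per stereoisomer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import Trajectory
from .osp import PerturbationSeries
from .stereo import code_to_identity

__all__ = ["read_timeseries", "write_timeseries", "TimeSeriesError"]


class TimeSeriesError(ValueError):
    """Malformed time-series file (reported with line numbers)."""


def write_timeseries(trajectory: Trajectory, path,
                     perturbation: PerturbationSeries | None = None,
                     pose: str | None = None) -> None:
    n = trajectory.n_frames
    cols: dict[str, np.ndarray] = {"step": np.arange(n)}
    for k in range(trajectory.xi.shape[1]):
        cols[f"xi{k+1}"] = trajectory.xi[:, k]
    for j in range(trajectory.phi.shape[1]):
        cols[f"phi{j+1}"] = trajectory.phi[:, j]
    for j in range(trajectory.theta.shape[1]):
        cols[f"theta{j+1}"] = trajectory.theta[:, j]
    if trajectory.distances is not None:
        for x in range(4):
            cols[f"dHC{x+1}"] = trajectory.distances[:, x]
    if perturbation is not None:
        for t, target in enumerate(perturbation.targets):
            cols[f"dH_{target.code}"] = perturbation.dH[:, t]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# dt_ps\t{trajectory.dt_ps!r}\n")
        fh.write(f"# reference_level\t{trajectory.reference_level}\n")
        if pose is not None:
            fh.write(f"# pose\t{pose}\n")
        if trajectory.seed is not None:
            fh.write(f"# seed\t{trajectory.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_timeseries(path) -> tuple[Trajectory, PerturbationSeries | None, dict]:
    """Parse a time-series file; returns (trajectory, perturbation, metadata).

    Raises :class:`TimeSeriesError` naming the offending channel or line for
    missing mandatory channels, non-numeric cells or ragged rows.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for ln_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise TimeSeriesError(
                    f"{path}:{ln_no}: expected {len(header)} columns, "
                    f"got {len(cells)}")
            rows.append(cells)
    if header is None or not rows:
        raise TimeSeriesError(f"{path}: no data rows")
    try:
        data = np.array(rows, dtype=float)
    except ValueError:
        for ln_off, r in enumerate(rows):
            for cell in r:
                try:
                    float(cell)
                except ValueError:
                    raise TimeSeriesError(
                        f"{path}: non-numeric cell {cell!r} in data row "
                        f"{ln_off + 1}") from None
        raise
    col = {name: i for i, name in enumerate(header)}
    for mandatory in ("step", "xi1", "xi2", "xi3", "xi4", "xi5"):
        if mandatory not in col:
            raise TimeSeriesError(f"{path}: missing mandatory channel "
                                  f"{mandatory!r}")
    steps = data[:, col["step"]]
    if np.any(np.diff(steps) <= 0):
        raise TimeSeriesError(f"{path}: step index must increase monotonically")
    xi = data[:, [col[f"xi{k}"] for k in range(1, 6)]]
    phi_names = sorted((c for c in col if re.fullmatch(r"phi\d+", c)),
                       key=lambda s: int(s[3:]))
    theta_names = sorted((c for c in col if re.fullmatch(r"theta\d+", c)),
                         key=lambda s: int(s[5:]))
    phi = data[:, [col[c] for c in phi_names]] if phi_names \
        else np.zeros((len(rows), 0))
    theta = data[:, [col[c] for c in theta_names]] if theta_names \
        else np.zeros((len(rows), 0))
    dist = None
    if all(f"dHC{x}" in col for x in range(1, 5)):
        dist = data[:, [col[f"dHC{x}"] for x in range(1, 5)]]
    traj = Trajectory(
        xi=xi, phi=phi, theta=theta,
        dt_ps=float(meta.get("dt_ps", 0.5)),
        reference_level=meta.get("reference_level", "ab"),
        seed=int(meta["seed"]) if "seed" in meta else None,
        distances=dist,
    )
    pert = None
    dh_names = [c for c in header if c.startswith("dH_")]
    if dh_names:
        targets = tuple(code_to_identity(c[3:]) for c in dh_names)
        dH = data[:, [col[c] for c in dh_names]]
        pert = PerturbationSeries(targets, dH, traj.reference_level)
    return traj, pert, meta
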