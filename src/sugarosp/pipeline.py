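"""End-to-end orchestration: trajectories in, comparison tables out.

Mirrors the production workflow: softened-reference trajectories from
vacuum, water and bound (pose A / pose B) environments are filtered for
unbound excursions, their perturbation energies evaluated, free energies
estimated per stereoisomer and combined across references, and the derived
tables (solvation, anomer, binding, reactive fractions, enantiomer and
occurrence reports) are written as CSV.  Deterministic given inputs and
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import compare, osp, reweight
from .sampler import Trajectory
from .stereo import (
    SugarIdentity,
    SugarTopology,
    ThermoConditions,
    all_identities,
    reference_topology,
)

logger = logging.getLogger("sugarosp")

__all__ = ["RunConfig", "estimate_states", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Pipeline parameters; all physical values positive."""

    temperature: float = 300.0
    experimental_temperature: float = 303.15
    cutoff_nm: float = reweight.REACTIVE_CUTOFF_NM
    min_lifetime_ps: float = 1.0
    unbound_threshold_nm: float = 1.5
    unbound_sustained_ps: float = 100.0
    reference_levels: tuple[str, ...] = ("a", "ab", "abc")
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("temperature", "experimental_temperature", "cutoff_nm",
                     "min_lifetime_ps", "unbound_threshold_nm",
                     "unbound_sustained_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def conditions(self) -> ThermoConditions:
        return ThermoConditions(self.temperature)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reference_levels" in raw:
            raw["reference_levels"] = tuple(raw["reference_levels"])
        return cls(**raw)


def _identity_frame(estimates: dict[int, osp.FreeEnergyEstimate]) -> pd.DataFrame:
    rows = []
    for ident in all_identities():
        est = estimates[ident.index]
        rows.append({
            "index": ident.index, "code": str(ident.code),
            "anomer": ident.anomer, "series": ident.series,
            "base_name": ident.base_name, "value": est.value,
            "stderr": est.stderr, "unsampled": est.unsampled,
        })
    return pd.DataFrame(rows)


def estimate_states(trajectories: Sequence[Trajectory],
                    levels: Sequence[str],
                    conditions: ThermoConditions,
                    common_level: str | None = None,
                    ) -> dict[int, osp.FreeEnergyEstimate]:
    """Per-state free energies from one or more reference trajectories.

    Each trajectory is analysed against its own reference Hamiltonian; with
    several references the estimates are transferred to a common reference
    (the first level) and combined exponentially.
    """
    if len(trajectories) != len(levels):
        raise ValueError("one reference level per trajectory is required")
    common = common_level or levels[0]
    r_common = reference_topology(common)
    per_state: dict[int, list[osp.FreeEnergyEstimate]] = {i: [] for i in range(1, 33)}
    for traj, level in zip(trajectories, levels):
        ref = reference_topology(level)
        series = osp.perturbation_energy_series(traj, ref)
        if level == common:
            for t, target in enumerate(series.targets):
                per_state[target.index].append(
                    osp.zwanzig(series.dH[:, t], conditions, state=target.name))
        else:
            for target in series.targets:
                per_state[target.index].append(
                    osp.reweight_free_energy(traj, ref, r_common, target,
                                             conditions))
    return {
        i: (ests[0] if len(ests) == 1
            else osp.combine_references(ests, conditions))
        for i, ests in per_state.items()
    }


def run_pipeline(config: RunConfig,
                 vacuum: Sequence[tuple[Trajectory, str]],
                 water: Sequence[tuple[Trajectory, str]],
                 bound: dict[str, Sequence[tuple[Trajectory, str]]],
                 monitors: dict[str, dict[str, np.ndarray]] | None = None,
                 ) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns and writes the report tables.

    ``vacuum``/``water``/``bound[pose]`` are (trajectory, reference_level)
    pairs; ``monitors`` optionally maps a bound-trajectory key
    ``f"{pose}:{i}"`` to named distance series used for unbound filtering.
    Pose A and pose B are analysed separately throughout and never merged.
    """
    conditions = config.conditions
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def estimates_of(pairs):
        trajs = [t for t, _ in pairs]
        levels = [lv for _, lv in pairs]
        return _identity_frame(estimate_states(trajs, levels, conditions))

    vac_df = estimates_of(vacuum)
    wat_df = estimates_of(water)
    solv = vac_df[["index", "value", "stderr"]].merge(
        wat_df[["index", "value", "stderr"]], on="index",
        suffixes=("_vac", "_water"))
    solv = compare.relative_solvation(
        solv[["index", "value_vac", "stderr_vac"]].rename(
            columns={"value_vac": "value", "stderr_vac": "stderr"}),
        solv[["index", "value_water", "stderr_water"]].rename(
            columns={"value_water": "value", "stderr_water": "stderr"}))

    anomers = compare.anomer_table(wat_df)
    reports: dict[str, pd.DataFrame] = {
        "vacuum_estimates": vac_df,
        "water_estimates": wat_df,
        "solvation": solv,
        "anomers": anomers,
        "enantiomers_vacuum": compare.enantiomer_report(vac_df),
        "enantiomers_water": compare.enantiomer_report(wat_df),
    }

    binding_frames = []
    exclusions = []
    for pose, pairs in bound.items():
        kept, dropped = [], []
        for i, (traj, level) in enumerate(pairs):
            key = f"{pose}:{i}"
            flag = reweight.UnboundFlag(True, None, None)
            if monitors and key in monitors:
                flag = reweight.flag_unbound(
                    monitors[key], traj.dt_ps,
                    threshold_nm=config.unbound_threshold_nm,
                    sustained_ps=config.unbound_sustained_ps)
            if flag.keep:
                kept.append((traj, level))
            else:
                dropped.append((key, flag))
                logger.info("excluding %s: unbound from %.1f ps (%s)",
                            key, flag.first_violation_ps, flag.channel)
        if not kept:
            raise PipelineError(
                f"all bound trajectories for pose {pose} were flagged "
                "unbound; nothing to analyse")
        exclusions.extend(
            {"pose": pose, "trajectory": k, "onset_ps": f.first_violation_ps,
             "channel": f.channel} for k, f in dropped)
        df = estimates_of(kept)
        df["pose"] = pose
        df = df.merge(wat_df[["index", "value", "stderr"]], on="index",
                      suffixes=("", "_water"))
        df["ddg_bind"] = df["value"] - df["value_water"]
        df["ddg_bind_err"] = np.hypot(df["stderr"], df["stderr_water"])
        binding_frames.append(df)
        reports[f"enantiomers_pose{pose}"] = compare.enantiomer_report(df)

        # reweighted reactive fractions where probe distances are present
        frac_rows = []
        ref0 = reference_topology(kept[0][1])
        for traj, level in kept:
            if traj.distances is None:
                continue
            series = osp.perturbation_energy_series(
                traj, reference_topology(level))
            for target in series.targets:
                dH = series.column(target)
                for site in range(4):
                    rf = reweight.reactive_fraction(
                        traj.distances[:, site], dH, conditions,
                        cutoff=config.cutoff_nm)
                    frac_rows.append({
                        "pose": pose, "index": target.index,
                        "state": target.name, "site": f"HC{site+1}",
                        "fraction": rf.value, "stderr": rf.stderr,
                    })
        if frac_rows:
            reports[f"reactive_fractions_pose{pose}"] = pd.DataFrame(frac_rows)

        # occurrence statistics of the pooled classified frames
        pooled = np.concatenate([osp.classify_frames(t) for t, _ in kept])
        occ = osp.occurrence_stats(pooled, kept[0][0].dt_ps,
                                   config.min_lifetime_ps)
        reports[f"occurrences_pose{pose}"] = pd.DataFrame({
            "index": np.arange(1, 33),
            "time_fraction": occ.time_fraction,
            "qualifying_runs": occ.qualifying_runs,
        })

    if binding_frames:
        reports["binding"] = pd.concat(binding_frames, ignore_index=True)
    reports["exclusions"] = pd.DataFrame(
        exclusions, columns=["pose", "trajectory", "onset_ps", "channel"])

    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    return reports
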