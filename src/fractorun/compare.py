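"""Validation harness: deterministic recurrence vs stochastic simulation.

Runs replicate simulations of a scenario, tallies the proportions of event
types (A, B, C, D, E, other) in windows of 1 - theta, runs the recurrence
for the same (mu, phi), and aligns the two on the 1 - theta axis — the
natural clock of the fractionation process.  Reports per-type deviations
and flags the regime where unmodeled >= 3-run mergers ("other") stop being
negligible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .recurrence import RecurrenceConfig, run_recurrence, RecurrenceTrajectory
from .simulator import DeletionModel, SimConfig, Trajectory, run_simulation

__all__ = ["ScenarioSpec", "ComparisonReport", "compare_recurrence_to_simulation"]

_TYPES = ("pA", "pB", "pC", "pD", "pE", "p_other")


@dataclass
class ScenarioSpec:
    name: str
    mu: float
    phi: float
    length: int = 100_000
    stop_theta: float = 0.1
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        DeletionModel(self.mu, self.phi)  # parameter validation

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)

    def to_json(self, path) -> None:
        doc = {
            "name": self.name,
            "mu": self.mu,
            "phi": self.phi,
            "length": self.length,
            "stop_theta": self.stop_theta,
            "replicates": self.replicates,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class ComparisonReport:
    spec: ScenarioSpec
    checkpoints: np.ndarray  # strictly increasing 1 - theta grid
    sim_mean: pd.DataFrame  # rows = checkpoints, columns = event types
    sim_se: pd.DataFrame
    recurrence: pd.DataFrame
    deviation: pd.DataFrame
    max_abs_deviation: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)
    other_regime_start: float | None = None  # first 1-theta with p_other > 0.05

    def to_frame(self) -> pd.DataFrame:
        out = {"one_minus_theta": self.checkpoints}
        for t in _TYPES:
            out[f"sim_{t}"] = self.sim_mean[t].to_numpy()
            out[f"sim_se_{t}"] = self.sim_se[t].to_numpy()
            out[f"rec_{t}"] = self.recurrence[t].to_numpy()
        return pd.DataFrame(out)


def _sim_proportions(traj: Trajectory, edges: np.ndarray) -> np.ndarray:
    """Event-type proportions per (edges[i], edges[i+1]] window of 1-theta."""
    out = np.full((edges.size - 1, 6), np.nan)
    frac = 1.0 - traj.events["theta"].to_numpy()
    types = traj.events["type"].to_numpy()
    which = np.searchsorted(edges, frac, side="left") - 1
    for b in range(edges.size - 1):
        t = types[which == b]
        if t.size:
            out[b] = np.bincount(t, minlength=6) / t.size
    return out


def compare_recurrence_to_simulation(
    spec: ScenarioSpec,
    config: RecurrenceConfig | None = None,
    checkpoints: np.ndarray | None = None,
    tolerance: float = 0.08,
    other_threshold: float = 0.05,
) -> ComparisonReport:
    """Align recurrence and replicate-simulation event-type trajectories.

    ``checkpoints`` are window midpoints on the 1 - theta axis (defaults to
    0.05 .. 1-stop_theta in steps of 0.05); simulation proportions are
    tallied per window (mean and standard error over replicates), the
    recurrence is interpolated linearly at the midpoints.  Entries whose
    absolute deviation exceeds ``tolerance`` are flagged.
    """
    if checkpoints is None:
        hi = 1.0 - spec.stop_theta
        checkpoints = np.arange(0.05, hi + 1e-9, 0.05)
    checkpoints = np.asarray(checkpoints, dtype=float)
    if np.any(np.diff(checkpoints) <= 0):
        raise ValueError("checkpoints must be strictly increasing in 1-theta")
    edges = np.concatenate(
        [
            [max(0.0, checkpoints[0] - (checkpoints[1] - checkpoints[0]) / 2)]
            if checkpoints.size > 1
            else [0.0],
            (checkpoints[:-1] + checkpoints[1:]) / 2,
            [checkpoints[-1] + (checkpoints[-1] - checkpoints[-2]) / 2]
            if checkpoints.size > 1
            else [1.0],
        ]
    )

    per_rep = np.full((spec.replicates, checkpoints.size, 6), np.nan)
    for rep in range(spec.replicates):
        cfg = SimConfig(
            length=spec.length,
            model=DeletionModel(mu=spec.mu, phi=spec.phi),
            seed=(spec.seed + 10_007 * rep) % (2**31),
            stop_theta=spec.stop_theta,
        )
        traj = run_simulation(cfg)
        per_rep[rep] = _sim_proportions(traj, edges)

    with np.errstate(invalid="ignore"):
        sim_mean = np.nanmean(per_rep, axis=0)
        sim_sd = np.nanstd(per_rep, axis=0, ddof=1)
        n_eff = np.sum(~np.isnan(per_rep[:, :, 0]), axis=0)
    sim_se = sim_sd / np.sqrt(np.maximum(n_eff, 1))[:, None]

    if config is None:
        config = RecurrenceConfig(
            mu=spec.mu, phi=spec.phi, theta_stop=min(spec.stop_theta, 0.09)
        )
    rec_traj: RecurrenceTrajectory = run_recurrence(config)
    rec = np.column_stack(
        [rec_traj.interp(checkpoints, t) for t in _TYPES]
    )

    sim_mean_df = pd.DataFrame(sim_mean, columns=_TYPES)
    sim_se_df = pd.DataFrame(sim_se, columns=_TYPES)
    rec_df = pd.DataFrame(rec, columns=_TYPES)
    dev_df = (rec_df - sim_mean_df).abs()

    max_dev = {t: float(np.nanmax(dev_df[t].to_numpy())) for t in _TYPES}
    flagged = [
        (float(checkpoints[i]), t)
        for t in _TYPES
        for i in np.flatnonzero(dev_df[t].to_numpy() > tolerance)
    ]
    other = sim_mean_df["p_other"].to_numpy()
    above = np.flatnonzero(np.nan_to_num(other) > other_threshold)
    other_start = float(checkpoints[above[0]]) if above.size else None

    return ComparisonReport(
        spec=spec,
        checkpoints=checkpoints,
        sim_mean=sim_mean_df,
        sim_se=sim_se_df,
        recurrence=rec_df,
        deviation=dev_df,
        max_abs_deviation=max_dev,
        flagged=flagged,
        other_regime_start=other_start,
    )
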