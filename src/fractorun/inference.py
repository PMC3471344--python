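"""Inference of the deletion-length mean mu and fractionation bias phi.

Only two kinds of quantity survive in data: the lengths l of single-copy
runs (after consolidating the two homeologous regions) and the proportion
theta of genes still in duplicate.  The per-run event count r is hidden.
The bias phi has a direct estimator — the share of single-copy genes lost
from each homeolog — while mu is recovered by matching either the mean run
length ("mean_curve") or the whole run-length histogram ("distribution")
against forward simulations of the excision model at the observed theta,
over a grid of candidate mu.  At fixed theta and phi the model mean run
length is strictly increasing in mu, which is what makes the inversion
well posed.

phi is reported on [0.5, 1] with a side label: the data cannot tell
(phi, 1 - phi) apart without an external chromosome-identity convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomePair, extract_runs
from .simulator import DeletionModel, SimConfig, run_simulation

__all__ = [
    "ObservedSample",
    "PhiEstimate",
    "FitResult",
    "ForwardModel",
    "estimate_phi_direct",
    "fit_mu_phi",
    "UnidentifiableWarning",
]


class UnidentifiableWarning(UserWarning):
    """The fit objective is nearly flat across the grid."""


@dataclass
class ObservedSample:
    """Observable run statistics of a consolidated homeologous pair.

    ``singles_on_1`` / ``singles_on_2`` count single-copy genes whose
    surviving copy sits on homeolog 1 / 2 — i.e. genes deleted from the
    *other* homeolog.  They are optional (0 when chromosome identity is not
    tracked); their sum, when present, equals the total single-copy gene
    count ``sum(run_lengths)``.
    """

    run_lengths: np.ndarray
    theta: float
    singles_on_1: int = 0
    singles_on_2: int = 0

    def __post_init__(self):
        self.run_lengths = np.asarray(self.run_lengths, dtype=np.int64)
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must be in (0, 1)")
        total = self.singles_on_1 + self.singles_on_2
        if total and total != int(self.run_lengths.sum()):
            raise ValueError(
                "singles_on_1 + singles_on_2 must equal sum(run_lengths)"
            )

    @classmethod
    def from_pair(cls, pair: GenomePair) -> "ObservedSample":
        _, stats = extract_runs(pair)
        on_1 = int(np.sum((pair.g == 1) & (pair.h == 0)))
        on_2 = int(np.sum((pair.g == 0) & (pair.h == 1)))
        return cls(
            run_lengths=stats.run_lengths,
            theta=stats.theta,
            singles_on_1=on_1,
            singles_on_2=on_2,
        )

    @property
    def mean_run_length(self) -> float:
        return float(self.run_lengths.mean())


@dataclass(frozen=True)
class PhiEstimate:
    phi_hat: float
    side: int  # homeolog that suffered the larger share of deletions


@dataclass
class FitResult:
    mu_hat: float
    phi_hat: float
    phi_side: int
    method: str
    objective_surface: pd.DataFrame  # columns mu, phi, objective
    ci_mu: tuple[float, float] | None = None
    ci_phi: tuple[float, float] | None = None
    replicates: int = 0
    seed: int = 0


def estimate_phi_direct(sample: ObservedSample) -> PhiEstimate:
    """phi from the per-homeolog split of single-copy genes.

    c_i = genes deleted FROM homeolog i = single-copy genes surviving on the
    other; phi_hat = max(c1, c2) / (c1 + c2), with the dominant homeolog
    reported as ``side``.
    """
    c1 = sample.singles_on_2  # survivor on 2 => deleted from 1
    c2 = sample.singles_on_1
    if c1 + c2 == 0:
        raise ValueError("no single-copy genes: phi is not estimable")
    if c1 >= c2:
        return PhiEstimate(phi_hat=c1 / (c1 + c2), side=1)
    return PhiEstimate(phi_hat=c2 / (c1 + c2), side=2)


def _derived_seed(seed: int, *parts: float) -> int:
    h = int(seed) & 0x7FFFFFFF
    for p in parts:
        h = (h * 1_000_003 + int(round(p * 4096.0))) & 0x7FFFFFFF
    return h


class ForwardModel:
    """Cache of forward-simulated run-length samples at a fixed theta.

    For each (mu, phi) grid point, ``n_rep`` replicate simulations of length
    ``length`` are stopped at the target theta and their single-copy run
    lengths pooled.  All replicate seeds derive deterministically from
    ``seed``.
    """

    def __init__(
        self,
        theta: float,
        length: int = 100_000,
        n_rep: int = 6,
        seed: int = 0,
    ):
        if not (0.0 < theta < 1.0):
            raise ValueError("theta must be in (0, 1)")
        self.theta = theta
        self.length = length
        self.n_rep = n_rep
        self.seed = seed
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def run_lengths(self, mu: float, phi: float) -> np.ndarray:
        key = (float(mu), float(phi))
        if key not in self._cache:
            pooled = []
            for rep in range(self.n_rep):
                cfg = SimConfig(
                    length=self.length,
                    model=DeletionModel(mu=mu, phi=phi),
                    seed=_derived_seed(self.seed, mu, phi, rep),
                    stop_theta=self.theta,
                )
                traj = run_simulation(cfg)
                pooled.append(traj.checkpoints[-1].stats.run_lengths)
            self._cache[key] = np.concatenate(pooled)
        return self._cache[key]

    def mean_run_length(self, mu: float, phi: float) -> float:
        return float(self.run_lengths(mu, phi).mean())

    def histogram(self, mu: float, phi: float, edges: np.ndarray) -> np.ndarray:
        x = self.run_lengths(mu, phi)
        counts, _ = np.histogram(x, bins=edges)
        return counts / max(counts.sum(), 1)


def _hist_edges(sample: ObservedSample) -> np.ndarray:
    """Unit bins up to the observed 95th percentile, then one tail bin."""
    b = int(np.quantile(sample.run_lengths, 0.95)) + 1
    b = int(np.clip(b, 6, 80))
    return np.concatenate([np.arange(1, b + 1), [np.inf]]).astype(float)


def _chi2_distance(p_obs: np.ndarray, p_mod: np.ndarray) -> float:
    denom = p_mod + 1e-6
    return float(np.sum((p_obs - p_mod) ** 2 / denom))


def _interp_minimum(mu_grid: np.ndarray, obj: np.ndarray) -> float:
    """Parabolic interpolation of the argmin on the log-mu axis."""
    i = int(np.argmin(obj))
    if i == 0 or i == len(mu_grid) - 1:
        return float(mu_grid[i])
    x = np.log(mu_grid[i - 1 : i + 2])
    y = obj[i - 1 : i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom <= 0:
        return float(mu_grid[i])
    shift = 0.5 * (y[0] - y[2]) / denom * (x[2] - x[0]) / 2.0
    xm = np.clip(np.log(mu_grid[i]) + shift, x[0], x[2])
    return float(np.exp(xm))


def fit_mu_phi(
    sample: ObservedSample,
    method: str = "distribution",
    mu_grid: Sequence[float] = (2.0, 3.0, 4.0, 6.0, 8.0, 11.0),
    phi_grid: Sequence[float] | None = None,
    length: int = 100_000,
    n_rep: int = 6,
    seed: int = 0,
    bootstrap: int = 0,
    ci_level: float = 0.90,
    forward: ForwardModel | None = None,
) -> FitResult:
    """Estimate (mu, phi) from run lengths and theta.

    ``mean_curve`` matches the observed mean run length against the forward
    model's mean over the mu grid (monotone inversion); ``distribution``
    minimizes a chi-square distance between run-length histograms.  When the
    sample carries per-homeolog counts, phi is first estimated directly and
    the mu fit runs at that phi; otherwise phi is gridded too.  Bootstrap
    intervals resample runs with replacement (theta held fixed) and re-fit
    against the cached model surface.
    """
    if method not in ("mean_curve", "distribution"):
        raise ValueError("method must be 'mean_curve' or 'distribution'")
    mu_grid = np.asarray(sorted(mu_grid), dtype=float)

    have_sides = (sample.singles_on_1 + sample.singles_on_2) > 0
    if have_sides:
        direct = estimate_phi_direct(sample)
        phi_values = np.array([direct.phi_hat])
        phi_side = direct.side
    else:
        phi_values = np.asarray(
            sorted(phi_grid if phi_grid is not None else (0.5, 0.75, 1.0)),
            dtype=float,
        )
        phi_side = 1

    if forward is None:
        forward = ForwardModel(
            theta=sample.theta, length=length, n_rep=n_rep, seed=seed
        )

    edges = _hist_edges(sample)
    obs_counts, _ = np.histogram(sample.run_lengths, bins=edges)
    obs_hist = obs_counts / max(obs_counts.sum(), 1)
    obs_mean = sample.mean_run_length

    def objective_row(mu: float, phi: float) -> float:
        if method == "mean_curve":
            return (forward.mean_run_length(mu, phi) - obs_mean) ** 2
        return _chi2_distance(obs_hist, forward.histogram(mu, phi, edges))

    rows = []
    for phi in phi_values:
        for mu in mu_grid:
            rows.append(
                {"mu": mu, "phi": phi, "objective": objective_row(mu, phi)}
            )
    surface = pd.DataFrame(rows)

    best_phi_idx = (
        surface.groupby("phi")["objective"].min().idxmin()
        if len(phi_values) > 1
        else phi_values[0]
    )
    sub = surface[surface["phi"] == best_phi_idx].sort_values("mu")
    obj = sub["objective"].to_numpy()

    spread = obj.max() - obj.min()
    if spread < 1e-12 or (obj.min() > 0 and spread / max(obj.min(), 1e-300) < 1e-3):
        warnings.warn(
            "objective is nearly flat over the mu grid; mu is weakly identified",
            UnidentifiableWarning,
        )

    if method == "mean_curve":
        means = np.array(
            [forward.mean_run_length(mu, best_phi_idx) for mu in mu_grid]
        )
        if np.all(np.diff(means) > 0):
            mu_hat = float(
                np.interp(obs_mean, means, mu_grid, left=mu_grid[0], right=mu_grid[-1])
            )
        else:
            mu_hat = _interp_minimum(mu_grid, obj)
    else:
        mu_hat = _interp_minimum(mu_grid, obj)

    phi_hat = float(best_phi_idx)
    if phi_hat < 0.5:
        phi_hat = 1.0 - phi_hat
        phi_side = 3 - phi_side

    ci_mu = ci_phi = None
    if bootstrap > 0:
        rng = np.random.default_rng(_derived_seed(seed, 777))
        mu_bs = np.empty(bootstrap)
        phi_bs = np.empty(bootstrap)
        n_runs = sample.run_lengths.size
        c_tot = sample.singles_on_1 + sample.singles_on_2
        p1 = sample.singles_on_1 / c_tot if c_tot else 0.5
        means_cache = (
            np.array([forward.mean_run_length(mu, best_phi_idx) for mu in mu_grid])
            if method == "mean_curve"
            else None
        )
        hists_cache = (
            [forward.histogram(mu, best_phi_idx, edges) for mu in mu_grid]
            if method == "distribution"
            else None
        )
        for b in range(bootstrap):
            res = sample.run_lengths[rng.integers(0, n_runs, n_runs)]
            if method == "mean_curve":
                om = float(res.mean())
                if np.all(np.diff(means_cache) > 0):
                    mu_bs[b] = float(
                        np.interp(
                            om,
                            means_cache,
                            mu_grid,
                            left=mu_grid[0],
                            right=mu_grid[-1],
                        )
                    )
                else:
                    o = (means_cache - om) ** 2
                    mu_bs[b] = _interp_minimum(mu_grid, o)
            else:
                cnt, _ = np.histogram(res, bins=edges)
                oh = cnt / max(cnt.sum(), 1)
                o = np.array([_chi2_distance(oh, hmod) for hmod in hists_cache])
                mu_bs[b] = _interp_minimum(mu_grid, o)
            if c_tot:
                c1 = rng.binomial(c_tot, p1)
                phi_bs[b] = max(c1, c_tot - c1) / c_tot
            else:
                phi_bs[b] = phi_hat
        alpha = (1.0 - ci_level) / 2.0
        ci_mu = tuple(np.quantile(mu_bs, [alpha, 1.0 - alpha]))
        ci_phi = tuple(np.quantile(phi_bs, [alpha, 1.0 - alpha]))

    return FitResult(
        mu_hat=mu_hat,
        phi_hat=phi_hat,
        phi_side=phi_side,
        method=method,
        objective_surface=surface,
        ci_mu=ci_mu,
        ci_phi=ci_phi,
        replicates=bootstrap,
        seed=seed,
    )
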