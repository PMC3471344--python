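"""Stochastic simulation of fractionation by segmental excision.

The model: starting from two identical homeologous chromosomes, deletion
events arrive one at a time.  Each event picks a homeolog (chromosome 1
with probability ``phi``, the fractionation bias), an anchor uniform among
the genes still present in duplicate, and a length ``a`` drawn from a
geometric distribution with mean ``mu``.  Scanning rightward from the
anchor it converts ``a`` surviving copies to deleted, skipping positions
already excised from the same homeolog (they are invisible to the excision
machinery) and stopping — a blocking collision — at the first position
whose copy on the other homeolog is already gone, which preserves the
functional constraint g + h >= 1.

Time is discrete (one event per tick); the continuous-time intensity of
the underlying process only serializes events and is irrelevant once the
state is indexed by theta, the surviving duplicate proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .core import GenomePair, Run, RunStatistics, extract_runs

__all__ = [
    "DeletionModel",
    "SimConfig",
    "DeletionEvent",
    "EVENT_TYPE_NAMES",
    "draw_deletion_length",
    "choose_anchor",
    "apply_deletion",
    "replay",
    "run_simulation",
    "Checkpoint",
    "Trajectory",
]

EVENT_TYPE_NAMES = ("A", "B", "C", "D", "E", "other")


@dataclass(frozen=True)
class DeletionModel:
    """Deletion-length mean mu (>= 1) and fractionation bias phi in [0, 1].

    gamma(a) = (1/mu) (1 - 1/mu)^(a-1), a >= 1; phi is the probability an
    event falls on chromosome 1 (G), 1 - phi on chromosome 2 (H).
    """

    mu: float
    phi: float

    def __post_init__(self):
        if self.mu < 1.0:
            raise ValueError(f"mu must be >= 1, got {self.mu}")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")

    def gamma(self, a) -> np.ndarray:
        """Geometric deletion-length pmf at integer lengths a >= 1."""
        a = np.asarray(a, dtype=np.float64)
        p = 1.0 / self.mu
        return np.where(a >= 1, p * np.power(1.0 - p, a - 1.0), 0.0)


@dataclass
class SimConfig:
    length: int = 100_000
    model: DeletionModel = field(default_factory=lambda: DeletionModel(6.0, 0.5))
    seed: int = 0
    stop_theta: float = 0.1
    checkpoints: Sequence[float] = ()

    def __post_init__(self):
        if not (0.0 < self.stop_theta < 1.0):
            raise ValueError("stop_theta must be in (0, 1)")
        if self.length < 1000:
            raise ValueError("length must be >= 1000")


@dataclass(frozen=True)
class DeletionEvent:
    event_id: int
    chromosome: int
    anchor: int
    drawn_length: int
    deleted_positions: tuple[int, ...]
    blocked: bool
    skipped_count: int
    clipped: bool = False


@dataclass
class Checkpoint:
    theta: float
    stats: RunStatistics
    runs: list[Run]


@dataclass
class Trajectory:
    """Simulation output: final pair, per-event records, checkpoints."""

    config: SimConfig
    pair: GenomePair
    events: pd.DataFrame  # columns theta, type, chromosome, drawn, deleted, ...
    checkpoints: list[Checkpoint]
    saturated: bool = False

    def event_type_proportions(self, lo: float, hi: float) -> np.ndarray:
        """Proportions of event types A..other for events with 1-theta in (lo, hi]."""
        frac = 1.0 - self.events["theta"].to_numpy()
        sel = (frac > lo) & (frac <= hi)
        t = self.events["type"].to_numpy()[sel]
        if t.size == 0:
            return np.full(6, np.nan)
        return np.bincount(t, minlength=6) / t.size


def draw_deletion_length(model: DeletionModel, rng: np.random.Generator) -> int:
    """One draw of the geometric deletion length (inverse-CDF transform)."""
    if model.mu <= 1.0:
        return 1
    u = rng.random()
    return 1 + int(np.log1p(-u) / np.log(1.0 - 1.0 / model.mu))


def choose_anchor(pair: GenomePair, rng: np.random.Generator) -> int:
    """Uniform anchor among positions with both copies present."""
    dup = np.flatnonzero((pair.g == 1) & (pair.h == 1))
    if dup.size == 0:
        raise RuntimeError("saturated: no duplicate positions remain")
    return int(dup[rng.integers(0, dup.size)])


def apply_deletion(
    pair: GenomePair, chromosome: int, anchor: int, a: int, event_id: int = 0
) -> DeletionEvent:
    """Apply one deletion event with skip/block semantics; mutates ``pair``.

    Scans rightward from ``anchor`` on the chosen homeolog: positions already
    0 there are skipped without counting toward ``a``; the first position
    whose other-homeolog copy is 0 blocks the event; otherwise the position
    is converted 1 -> 0, until ``a`` conversions or the end of the interval.
    """
    if chromosome not in (1, 2):
        raise ValueError("chromosome must be 1 (G) or 2 (H)")
    if a < 1:
        raise ValueError("deletion length must be >= 1")
    if not (0 <= anchor < pair.length):
        raise ValueError(f"anchor {anchor} outside interval")
    if not (pair.g[anchor] == 1 and pair.h[anchor] == 1):
        raise ValueError(
            f"anchor {anchor} is not a duplicate position (g=h=1 required)"
        )
    mine = pair.g if chromosome == 1 else pair.h
    other = pair.h if chromosome == 1 else pair.g

    deleted: list[int] = []
    pos = anchor
    skipped = 0
    blocked = False
    while len(deleted) < a and pos < pair.length:
        if mine[pos] == 0:
            pos += 1
            skipped += 1
            continue
        if other[pos] == 0:
            blocked = True
            break
        mine[pos] = 0
        pair.ev_id[pos] = event_id
        pair.ev_chr[pos] = chromosome
        deleted.append(pos)
        pos += 1
    return DeletionEvent(
        event_id=event_id,
        chromosome=chromosome,
        anchor=anchor,
        drawn_length=a,
        deleted_positions=tuple(deleted),
        blocked=blocked,
        skipped_count=skipped,
        clipped=(len(deleted) < a and not blocked),
    )


def replay(
    pair: GenomePair, script: Sequence[tuple[int, int, int]]
) -> tuple[GenomePair, list[DeletionEvent], list[Run], RunStatistics]:
    """Deterministically apply scripted (chromosome, anchor, a) events.

    Raises ValueError naming the failing event index if a scripted anchor is
    invalid at its turn.
    """
    events = []
    for k, (chrom, anchor, a) in enumerate(script):
        try:
            events.append(apply_deletion(pair, chrom, anchor, a, event_id=k + 1))
        except ValueError as exc:
            raise ValueError(f"replay failed at event {k + 1}: {exc}") from exc
    runs, stats = extract_runs(pair)
    return pair, events, runs, stats


def run_simulation(config: SimConfig) -> Trajectory:
    """Simulate until theta <= stop_theta, recording requested checkpoints.

    Fully reproducible from ``config.seed``: a single PCG64 generator feeds
    the chromosome, anchor and length draws of every event, in that order.
    """
    n = config.length
    pair = GenomePair.identical(n)
    gen = np.random.default_rng(config.seed)

    targets = sorted(set(config.checkpoints) | {config.stop_theta}, reverse=True)
    targets = [t for t in targets if t >= config.stop_theta]

    cap = n  # every event deletes at least one position
    rec_theta = np.empty(cap, dtype=np.float64)
    rec_type = np.empty(cap, dtype=np.int8)
    rec_chrom = np.empty(cap, dtype=np.int8)
    rec_drawn = np.empty(cap, dtype=np.int64)
    rec_deleted = np.empty(cap, dtype=np.int64)
    rec_skipped = np.empty(cap, dtype=np.int64)
    rec_blocked = np.empty(cap, dtype=np.int8)
    rec_clipped = np.empty(cap, dtype=np.int8)

    dup_count = n
    next_eid = 1
    total = 0
    checkpoints: list[Checkpoint] = []
    saturated = False
    for target in targets:
        dup_count, next_eid, count = _kernel.run_until(
            pair.g,
            pair.h,
            pair.ev_id,
            pair.ev_chr,
            dup_count,
            next_eid,
            target,
            config.model.phi,
            config.model.mu,
            gen,
            rec_theta[total:],
            rec_type[total:],
            rec_chrom[total:],
            rec_drawn[total:],
            rec_deleted[total:],
            rec_skipped[total:],
            rec_blocked[total:],
            rec_clipped[total:],
        )
        total += count
        if dup_count == 0:
            saturated = True
        runs, stats = extract_runs(pair)
        checkpoints.append(Checkpoint(theta=stats.theta, stats=stats, runs=runs))
        if saturated:
            warnings.warn("simulation saturated before stop_theta", RuntimeWarning)
            break

    events = pd.DataFrame(
        {
            "theta": rec_theta[:total],
            "type": rec_type[:total],
            "chromosome": rec_chrom[:total],
            "drawn": rec_drawn[:total],
            "deleted": rec_deleted[:total],
            "skipped": rec_skipped[:total],
            "blocked": rec_blocked[:total],
            "clipped": rec_clipped[:total],
        }
    )
    return Trajectory(
        config=config,
        pair=pair,
        events=events,
        checkpoints=checkpoints,
        saturated=saturated,
    )
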