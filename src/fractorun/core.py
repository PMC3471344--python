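"""Shared domain types for post-WGD fractionation data.

After a whole genome duplication, a genome carries two homeologous copies
(G and H) of every chromosome.  Fractionation — the loss of one member of
each duplicate gene pair — leaves an interleaved presence/absence pattern
over the two homeologs.  This module holds the consolidated representation
of such a pair of regions as two binary sequences, extracts maximal runs of
single-copy genes, and computes the run statistics (theta, pi, tau, u_bar,
v_bar) that the simulator, the recurrence and the inference routines share.

Conventions: positions are 0-based and intervals half-open.  ``g[i]`` /
``h[i]`` are 1 while the copy on that homeolog survives, 0 once deleted.
The functional constraint of fractionation forbids ``g[i] == h[i] == 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConstraintViolationError",
    "UndefinedRatioError",
    "GenomePair",
    "Run",
    "RunStatistics",
    "extract_runs",
    "verify_accounting",
    "read_presence_absence",
    "write_presence_absence",
    "write_runs_tsv",
    "summary_dict",
]


class ConstraintViolationError(ValueError):
    """Both copies of a gene are absent (g(i) + h(i) = 0)."""

    def __init__(self, position: int):
        self.position = position
        super().__init__(
            f"g + h = 0 at position {position}: both copies of a duplicate "
            "pair may never be deleted"
        )


class UndefinedRatioError(ValueError):
    """The accounting identity is undefined at theta = 0 or theta = 1."""


@dataclass
class GenomePair:
    """Two homeologous binary presence sequences over a common interval.

    ``ev_id``/``ev_chr`` form the per-position event log: for every deleted
    position, the identifier of the deletion event that removed it and the
    homeolog (1 for G, 2 for H) it was removed from.  Positions still in
    duplicate carry ``ev_id = -1`` and ``ev_chr = 0``.  Observed data loaded
    without an event history get ``ev_id = -1`` everywhere; run event counts
    are then reported as 0 (unknown).
    """

    g: np.ndarray
    h: np.ndarray
    ev_id: np.ndarray
    ev_chr: np.ndarray

    @classmethod
    def identical(cls, length: int) -> "GenomePair":
        """Fresh post-WGD state: every gene present on both homeologs."""
        if length < 1:
            raise ValueError("length must be >= 1")
        return cls(
            g=np.ones(length, dtype=np.int8),
            h=np.ones(length, dtype=np.int8),
            ev_id=np.full(length, -1, dtype=np.int64),
            ev_chr=np.zeros(length, dtype=np.int8),
        )

    @classmethod
    def from_arrays(cls, g: Sequence[int], h: Sequence[int]) -> "GenomePair":
        """Build from observed 0/1 vectors, deriving ev_chr from the pattern."""
        g = np.asarray(g, dtype=np.int8)
        h = np.asarray(h, dtype=np.int8)
        if g.shape != h.shape or g.ndim != 1:
            raise ValueError("g and h must be 1-D arrays of equal length")
        pair = cls(
            g=g,
            h=h,
            ev_id=np.full(g.shape[0], -1, dtype=np.int64),
            ev_chr=np.zeros(g.shape[0], dtype=np.int8),
        )
        pair.ev_chr[g == 0] = 1
        pair.ev_chr[h == 0] = 2
        pair.validate()
        return pair

    @property
    def length(self) -> int:
        return int(self.g.shape[0])

    @property
    def theta(self) -> float:
        """Proportion of positions still present in duplicate."""
        return float(np.mean((self.g + self.h) == 2))

    def validate(self) -> None:
        bad = np.flatnonzero((self.g + self.h) == 0)
        if bad.size:
            raise ConstraintViolationError(int(bad[0]))

    def copy(self) -> "GenomePair":
        return GenomePair(
            self.g.copy(), self.h.copy(), self.ev_id.copy(), self.ev_chr.copy()
        )


@dataclass(frozen=True)
class Run:
    """A maximal consolidated segment of single-copy genes.

    ``event_count`` is r, the number of distinct deletion events whose
    deleted positions lie in the run (0 when no event log is available).
    ``side_left``/``side_right`` name the homeolog (1=G, 2=H) of the
    leftmost/rightmost deleted term.
    """

    start: int
    length: int
    event_count: int
    both_chromosomes: bool
    side_left: int
    side_right: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("run length must be >= 1")
        if not self.both_chromosomes and self.side_left != self.side_right:
            raise ValueError("single-homeolog run with differing end sides")


@dataclass
class RunStatistics:
    """Aggregate run statistics of a consolidated pair.

    theta     proportion of duplicate positions,
    f         run-length frequencies f(l) of single-copy runs,
    pi        proportion pi(r) of runs produced by exactly r events,
    tau       proportion tau(r) of r-event runs with terms from both homeologs,
    u_bar     mean single-copy (deleted) run length,
    v_bar     mean duplicate (undeleted) run length,
    run_count number R of single-copy runs.
    """

    theta: float
    f: Mapping[int, int]
    pi: Mapping[int, float]
    tau: Mapping[int, float]
    u_bar: float
    v_bar: float
    run_count: int
    duplicate_run_count: int = 0
    tau_total: float = 0.0
    length: int = 0
    duplicate_run_lengths: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64), repr=False
    )
    run_lengths: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64), repr=False
    )


def _segments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and lengths of maximal True segments of a boolean vector."""
    if mask.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return starts.astype(np.int64), (ends - starts).astype(np.int64)


def extract_runs(pair: GenomePair) -> tuple[list[Run], RunStatistics]:
    """Consolidate G+H and return all maximal single-copy runs + statistics.

    The interval is linear; runs touching either boundary are included.
    Raises :class:`ConstraintViolationError` if any position has lost both
    copies.
    """
    pair.validate()
    n = pair.length
    s = pair.g.astype(np.int16) + pair.h.astype(np.int16)
    single = s == 1
    dup = ~single

    starts, lengths = _segments(single)
    _, dup_lengths = _segments(dup)
    nruns = starts.size

    theta = float(np.mean(dup))

    runs: list[Run] = []
    r_values = np.zeros(nruns, dtype=np.int64)
    both = np.zeros(nruns, dtype=bool)

    if nruns:
        idx = np.flatnonzero(single)
        run_of = np.repeat(np.arange(nruns, dtype=np.int64), lengths)
        ch = pair.ev_chr[idx]
        ev = pair.ev_id[idx]

        offs = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        side_left = ch[offs]
        side_right = ch[np.cumsum(lengths) - 1]
        ch_min = np.minimum.reduceat(ch, offs)
        ch_max = np.maximum.reduceat(ch, offs)
        both = (ch_min == 1) & (ch_max == 2)

        if np.any(ev >= 0):
            # each deletion event belongs to exactly one run, so distinct
            # (run, event) pairs count r per run
            key = run_of * (int(ev.max()) + 2) + ev
            uniq_runs = np.unique(key) // (int(ev.max()) + 2)
            r_values = np.bincount(uniq_runs, minlength=nruns).astype(np.int64)

        for j in range(nruns):
            runs.append(
                Run(
                    start=int(starts[j]),
                    length=int(lengths[j]),
                    event_count=int(r_values[j]),
                    both_chromosomes=bool(both[j]),
                    side_left=int(side_left[j]),
                    side_right=int(side_right[j]),
                )
            )

    f = {int(l): int(c) for l, c in zip(*np.unique(lengths, return_counts=True))}
    pi: dict[int, float] = {}
    tau: dict[int, float] = {}
    tau_total = 0.0
    if nruns and r_values.max() > 0:
        for r in np.unique(r_values):
            sel = r_values == r
            pi[int(r)] = float(np.mean(sel))
            tau[int(r)] = float(np.mean(both[sel]))
        tau_total = float(np.mean(both))

    stats = RunStatistics(
        theta=theta,
        f=f,
        pi=pi,
        tau=tau,
        u_bar=float(lengths.mean()) if nruns else float("nan"),
        v_bar=float(dup_lengths.mean()) if dup_lengths.size else float("nan"),
        run_count=int(nruns),
        duplicate_run_count=int(dup_lengths.size),
        tau_total=tau_total,
        length=n,
        duplicate_run_lengths=dup_lengths,
        run_lengths=lengths,
    )
    return runs, stats


def verify_accounting(stats: RunStatistics) -> float:
    """Residual of the run-accounting identity v_bar = theta/(1-theta) u_bar.

    Alternating runs of deleted and undeleted genes come in (nearly) equal
    numbers, so the total duplicate mass theta*N = R_v*v_bar and single-copy
    mass (1-theta)*N = R_u*u_bar force the identity up to at most two
    boundary runs on a finite interval.  Returns the signed residual; the
    caller bounds it by the edge slack 2*max(u_bar, v_bar)/run_count.
    """
    if not (0.0 < stats.theta < 1.0):
        raise UndefinedRatioError(
            f"accounting identity undefined at theta = {stats.theta}"
        )
    return stats.v_bar - stats.theta / (1.0 - stats.theta) * stats.u_bar


# ---------------------------------------------------------------------------
# plain-text interchange

def read_presence_absence(path) -> GenomePair:
    """Read a TSV with header columns position, g, h (0/1 entries)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("position", "g", "h"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    df = df.sort_values("position")
    pos = df["position"].to_numpy()
    if pos.size and np.any(np.diff(pos) != 1):
        raise ValueError("positions must form a contiguous interval")
    return GenomePair.from_arrays(df["g"].to_numpy(), df["h"].to_numpy())


def write_presence_absence(pair: GenomePair, path, offset: int = 0) -> None:
    df = pd.DataFrame(
        {
            "position": np.arange(pair.length) + offset,
            "g": pair.g.astype(int),
            "h": pair.h.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_runs_tsv(runs: Sequence[Run], path, offset: int = 0) -> None:
    df = pd.DataFrame(
        {
            "start": [r.start + offset for r in runs],
            "length": [r.length for r in runs],
            "r": [r.event_count for r in runs],
            "both_chromosomes": [int(r.both_chromosomes) for r in runs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def summary_dict(stats: RunStatistics) -> dict:
    """JSON-ready summary: theta, u_bar, v_bar and the pi/tau/f histograms."""
    return {
        "theta": stats.theta,
        "u_bar": stats.u_bar,
        "v_bar": stats.v_bar,
        "run_count": stats.run_count,
        "tau_total": stats.tau_total,
        "f": {str(k): v for k, v in sorted(stats.f.items())},
        "pi": {str(k): v for k, v in sorted(stats.pi.items())},
        "tau": {str(k): v for k, v in sorted(stats.tau.items())},
    }


def write_summary_json(stats: RunStatistics, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary_dict(stats), fh, indent=1, sort_keys=False)
        fh.write("\n")
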