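"""Deterministic recurrence for the run statistics of fractionation.

Instead of simulating individual deletion events, the state of the process
is summarized by the distribution pi(r) of deletion events per single-copy
run, the proportions tau(r) of r-event runs with content from both
homeologs, the mean deleted- and undeleted-run lengths u_bar and v_bar, and
the duplicate proportion theta.  Under the modeling assumption that
undeleted-run lengths are geometric with mean v_bar (and independent), the
probability that the next deletion event is of each structural type —

    A   creates a new run (touches no existing single-copy run),
    B   extends one run leftward-adjacent to the anchor,
    C   reaches the run to the right (blocked or overlapping),
    D   engulfs the run to the right and touches the next one,
    E   bridges the runs on both sides,

with chromosome sub-variants (same homeolog i..i vs cross i..f) — can be
written as sums over the run-length distributions rho and the geometric
deletion-length law gamma.  Feeding the expected per-event changes back
into pi, tau, u_bar, v_bar gives a deterministic trajectory in theta that
parallels the stochastic simulation without its noise.  Mergers of three
or more runs are not modeled; their probability is reported as ``p_other``
and never fed back.

Numerics: rho is truncated where its tail mass drops below
``tail_epsilon`` and renormalized; partial sums of gamma are exact
cumulative arrays (the geometric tail Sum_{a>=x} gamma(a) = (1-1/mu)^(x-1)
is closed-form); the inner sums over the second and third run lengths are
evaluated as (FFT) correlations, an exact reassociation of the nested
summations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

__all__ = [
    "RecurrenceConfig",
    "RecurrenceState",
    "EventRates",
    "StepSizeError",
    "TruncationError",
    "geometric_rho",
    "compute_rates",
    "delta_pi",
    "delta_tau",
    "advance",
    "run_recurrence",
    "RecurrenceTrajectory",
]


class StepSizeError(RuntimeError):
    """The macro-step produced an invalid state; use a smaller Lambda."""


class TruncationError(RuntimeError):
    """Support limits cannot hold the requested tail mass bound."""


@dataclass
class RecurrenceConfig:
    mu: float
    phi: float
    Lambda: float | None = None  # None = adaptive (<=1% run-count change/step)
    theta_start: float = 0.99
    theta_stop: float = 0.1
    tail_epsilon: float = 1e-10
    conservation_mode: str = "corrected"  # or "as_printed"
    literal_tau: bool = False  # audit flag: printed forms of the tau update
    r_max: int = 600
    l_max_cap: int = 500_000
    dtheta_max: float = 0.002
    max_steps: int = 100_000

    def __post_init__(self):
        if self.mu < 1.0:
            raise ValueError("mu must be >= 1")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must be in [0, 1]")
        if self.conservation_mode not in ("corrected", "as_printed"):
            raise ValueError("conservation_mode must be 'corrected' or 'as_printed'")
        if not (0.0 < self.tail_epsilon < 1.0):
            raise ValueError("tail_epsilon must be in (0, 1)")
        if self.Lambda is not None and self.Lambda <= 0:
            raise ValueError("Lambda must be positive")


@dataclass
class RecurrenceState:
    """pi, tau, u_bar, v_bar, theta and the run-count carrier R.

    R is an arbitrary positive normalization (it cancels in every reported
    proportion); pi sums to 1; tau[0] (r=1) is identically 0; v_bar equals
    theta/(1-theta) * u_bar at every step by construction.
    """

    pi: np.ndarray
    tau: np.ndarray
    u_bar: float
    v_bar: float
    theta: float
    R: float = 1.0

    @property
    def tau_total(self) -> float:
        return float(np.dot(self.tau, self.pi))

    @classmethod
    def initial(cls, config: RecurrenceConfig) -> "RecurrenceState":
        # The process cannot start at theta = 1 (no runs to describe).  Near
        # theta = 1 essentially every event is type A, so runs are fresh
        # single events: pi = (1, 0, ...), tau = 0, u_bar = mu and v_bar
        # follows from the accounting identity.
        theta = config.theta_start
        pi = np.zeros(config.r_max)
        pi[0] = 1.0
        tau = np.zeros(config.r_max)
        u = config.mu
        v = theta / (1.0 - theta) * u
        return cls(pi=pi, tau=tau, u_bar=u, v_bar=v, theta=theta, R=1.0)


@dataclass
class EventRates:
    """Per-event probabilities and mean-length contributions at a state.

    ``by_variant`` holds every chromosome-subscripted probability
    (pA1, pA2, pB11, pB12, ..., pEiff21); ``mu_by_family`` the aggregated
    mean-length contributions mu_A ... mu_Eiff.  ``p_other`` is the
    unmodeled residual (>= 3-run mergers), never fed back into pi.
    """

    pA: float
    pB: float
    pC: float
    pD: float
    pE: float
    p_other: float
    mu_total: float
    by_variant: dict = field(default_factory=dict)
    mu_by_family: dict = field(default_factory=dict)
    phi1: float = 0.5
    phi2: float = 0.5

    @property
    def cross_extension(self) -> float:
        """pB12 + pB21 + pC12 + pC21: extensions joining the two homeologs."""
        v = self.by_variant
        return v["pB12"] + v["pB21"] + v["pC12"] + v["pC21"]

    @property
    def total_modeled(self) -> float:
        return self.pA + self.pB + self.pC + self.pD + self.pE


def geometric_rho(
    v_bar: float, tail_epsilon: float = 1e-10, l_max_cap: int = 500_000
) -> tuple[np.ndarray, float]:
    """Truncated, renormalized geometric run-length law with mean v_bar.

    rho(l) = (1/v_bar)(1 - 1/v_bar)^(l-1) on l = 1..l_max, with l_max the
    smallest support whose discarded tail mass is below ``tail_epsilon``.
    Returns (rho, E_rho) with rho[0] = rho(1).
    """
    if v_bar < 1.0:
        raise ValueError(f"v_bar must be >= 1, got {v_bar}")
    if v_bar == 1.0 or (1.0 - 1.0 / v_bar) == 0.0:
        return np.array([1.0]), 1.0
    q = 1.0 - 1.0 / v_bar
    l_max = int(np.ceil(np.log(tail_epsilon) / np.log(q))) + 1
    if l_max > l_max_cap:
        raise TruncationError(
            f"l_max = {l_max} needed for tail mass {tail_epsilon} exceeds the "
            f"cap {l_max_cap}; raise l_max_cap or tail_epsilon"
        )
    l = np.arange(1, l_max + 1, dtype=np.float64)
    rho = (1.0 / v_bar) * q ** (l - 1.0)
    rho /= rho.sum()
    e_rho = float(np.dot(l, rho))
    return rho, e_rho


def _correlate(F: np.ndarray, w: np.ndarray) -> np.ndarray:
    """V[i] = sum_j F[i + j] w[j] for i = 0..len(F)-len(w) (exact reassociation).

    Direct summation for small supports, FFT for large ones.
    """
    if F.size * w.size <= 262_144:
        return np.correlate(F, w, mode="valid")
    return fftconvolve(F, w[::-1], mode="valid")


def compute_rates(state: RecurrenceState, config: RecurrenceConfig) -> EventRates:
    """Event-type probabilities and mean-length contributions at ``state``.

    The scalar tau entering the rate coefficients is the mixture total
    Sum_r tau(r) pi(r).
    """
    rho, e_rho = geometric_rho(
        state.v_bar, config.tail_epsilon, config.l_max_cap
    )
    return _rates_from_rho(
        rho, e_rho, config.mu, config.phi, state.tau_total
    )


def _rates_from_rho(
    rho: np.ndarray, e_rho: float, mu: float, phi: float, tau: float
) -> EventRates:
    """Rates for an explicit undeleted-run-length law rho (testing hook)."""
    L = rho.size
    p = 1.0 / mu
    s = 1.0 - p

    # tail sums of rho: Srho[x] = sum_{l >= x} rho(l), x = 0..L+1
    Srho = np.zeros(L + 2)
    Srho[1:L + 1] = np.cumsum(rho[::-1])[::-1]
    Srho[0] = Srho[1]

    # exact partial sums of the deletion-length law gamma over 0..X
    X = 3 * L + 3
    x = np.arange(X, dtype=np.float64)
    with np.errstate(divide="ignore"):
        gam = np.where(x >= 1, p * np.power(s, np.maximum(x - 1.0, 0.0)), 0.0)
    Gam = np.cumsum(gam)                 # Gamma(x) = sum_{a<=x} gamma(a)
    G1 = np.cumsum(x * gam)              # sum_{a<=x} a gamma(a)
    Sg = np.where(x >= 1, np.power(s, np.maximum(x - 1.0, 0.0)), 1.0)
    if mu == 1.0:
        Sg = np.where(x <= 1, 1.0, 0.0)  # survival of the point mass at 1

    # correlations over the second run length k (and third, h)
    CG = _correlate(Gam, rho)            # CG[m] = sum_k rho(k) Gamma(m+k-1)
    CG1 = _correlate(G1, rho)
    w2 = np.convolve(rho, rho)           # w2[j] = P[k + h = j + 2]
    CCG = _correlate(Gam[1:], w2)        # CCG[m] = sum_{k,h} Gamma(m+k+h-1)
    CCG1 = _correlate(G1[1:], w2)

    # scalar moments of rho against the gamma survival s^(k-1)
    k = np.arange(1, L + 1, dtype=np.float64)
    sk = np.power(s, k - 1.0) if mu > 1.0 else np.where(k == 1.0, 1.0, 0.0)
    Mrho = float(np.dot(rho, sk))
    M1rho = float(np.dot(rho, k * sk))

    # --- structural sums (chromosome-free parts) ---
    SA = SmuA = 0.0
    if L >= 3:
        l = np.arange(3, L + 1)
        li = l.astype(np.intp)
        G2 = np.cumsum(x * x * gam)
        SA = float(np.dot(rho[2:], (l - 1) * Gam[li - 2] - G1[li - 2]))
        SmuA = float(np.dot(rho[2:], (l - 1) * G1[li - 2] - G2[li - 2]))

    SB = SmuB = 0.0
    if L >= 2:
        l = np.arange(2, L + 1, dtype=np.intp)
        SB = float(np.dot(rho[1:], Gam[l - 1]))
        SmuB = float(np.dot(rho[1:], G1[l - 1]))

    SCii = SmuCii = SCif = SmuCif = 0.0
    SDiii = SmuDiii = SDiif = SmuDiif = 0.0
    if L >= 2:
        m = np.arange(1, L, dtype=np.intp)
        Sr = Srho[m + 1]
        mf = m.astype(np.float64)
        SCii = float(np.dot(Sr, CG[m] - Gam[m - 1]))
        SmuCii = float(np.dot(Sr, CG1[m] - G1[m - 1]))
        SCif = float(np.dot(Sr, Sg[m]))
        SmuCif = float(np.dot(Sr, mf * Sg[m]))
        SDiii = float(np.dot(Sr, CCG[m] - CG[m]))
        SmuDiii = float(np.dot(Sr, CCG1[m] - CG1[m]))
        sm = np.power(s, mf) if mu > 1.0 else np.zeros_like(mf)
        SDiif = float(np.dot(Sr, sm)) * Mrho
        SmuDiif = float(np.dot(Sr, sm * (mf * Mrho + M1rho)))

    l = np.arange(1, L + 1, dtype=np.intp)
    SEiii = float(np.dot(rho, CG[l] - Gam[l - 1]))
    SmuEiii = float(np.dot(rho, CG1[l] - G1[l - 1]))
    SEif_tail = Mrho
    SmuEif_tail = M1rho

    # --- chromosome coefficients ---
    phi1, phi2 = phi, 1.0 - phi
    s2 = phi1**2 + phi2**2
    s3 = phi1**3 + phi2**3
    cx = phi1 * phi2
    omt = 1.0 - tau
    E = e_rho

    v: dict[str, float] = {}
    v["pA1"] = phi1 * SA / E
    v["pA2"] = phi2 * SA / E
    for i, f, pi_, pf_ in (
        (1, 1, phi1, phi1),
        (1, 2, phi1, phi2),
        (2, 1, phi2, phi1),
        (2, 2, phi2, phi2),
    ):
        v[f"pB{i}{f}"] = pi_ * pf_ * SB / E
    v["pC11"] = phi1**2 * omt * SCii / E
    v["pC22"] = phi2**2 * omt * SCii / E
    v["pC12"] = (phi1 * tau + phi1 * phi2 * omt) * SCif / E
    v["pC21"] = (phi2 * tau + phi2 * phi1 * omt) * SCif / E
    v["pD111"] = phi1**3 * omt**2 * SDiii / E
    v["pD222"] = phi2**3 * omt**2 * SDiii / E
    v["pD112"] = (phi1**2 * omt * tau + phi1**2 * phi2 * omt**2) * SDiif / E
    v["pD221"] = (phi2**2 * omt * tau + phi2**2 * phi1 * omt**2) * SDiif / E
    v["pE111"] = phi1**3 * omt * SEiii / E
    v["pE222"] = phi2**3 * omt * SEiii / E
    v["pE112"] = (phi1**2 * tau + phi1**2 * phi2 * omt) * SEif_tail / E
    v["pE221"] = (phi2**2 * tau + phi2**2 * phi1 * omt) * SEif_tail / E
    v["pE121"] = phi1**2 * phi2 * omt * SEiii / E
    v["pE212"] = phi2**2 * phi1 * omt * SEiii / E
    v["pE122"] = (phi1 * phi2 * tau + phi1 * phi2**2 * omt) * SEif_tail / E
    v["pE211"] = (phi2 * phi1 * tau + phi2 * phi1**2 * omt) * SEif_tail / E

    pA = v["pA1"] + v["pA2"]
    pB = sum(v[k_] for k_ in ("pB11", "pB12", "pB21", "pB22"))
    pC = sum(v[k_] for k_ in ("pC11", "pC22", "pC12", "pC21"))
    pD = sum(v[k_] for k_ in ("pD111", "pD222", "pD112", "pD221"))
    pE = sum(
        v[k_]
        for k_ in (
            "pE111", "pE222", "pE112", "pE221",
            "pE121", "pE212", "pE122", "pE211",
        )
    )

    mu_fam = {
        "A": SmuA / E,
        "B": SmuB / E,
        "Cii": s2 * omt * SmuCii / E,
        "Cif": (tau + 2 * cx * omt) * SmuCif / E,
        "Diii": s3 * omt**2 * SmuDiii / E,
        "Diif": (s2 * omt * tau + cx * omt**2) * SmuDiif / E,
        "Eiii": s3 * omt * SmuEiii / E,
        "Eiif": (s2 * tau + cx * omt) * SmuEif_tail / E,
        "Eifi": cx * omt * SmuEiii / E,
        "Eiff": (2 * cx * tau + cx * omt) * SmuEif_tail / E,
    }
    mu_total = float(sum(mu_fam.values()))

    p_other = max(0.0, 1.0 - (pA + pB + pC + pD + pE))
    return EventRates(
        pA=pA,
        pB=pB,
        pC=pC,
        pD=pD,
        pE=pE,
        p_other=p_other,
        mu_total=mu_total,
        by_variant=v,
        mu_by_family=mu_fam,
        phi1=phi1,
        phi2=phi2,
    )


def delta_pi(
    rates: EventRates, pi: np.ndarray, conservation_mode: str = "corrected"
) -> np.ndarray:
    """Expected per-event change in the count of r-event runs.

    New runs appear at r=1 (type A); extensions move runs r -> r+1 (B, C);
    a merger consumes runs of r and s and produces one with r+s+1 events.
    In "corrected" mode the merger gain term carries coefficient pD+pE (one
    run produced per merger, two consumed, net -1); "as_printed" uses the
    literal 2(pD+pE), under which the total run count grows by pA per event.
    """
    ext = rates.pB + rates.pC
    loss = ext + 2.0 * (rates.pD + rates.pE)
    gmerge = (
        rates.pD + rates.pE
        if conservation_mode == "corrected"
        else 2.0 * (rates.pD + rates.pE)
    )
    d = -loss * pi
    d[0] += rates.pA
    if pi.size > 1:
        d[1:] += ext * pi[:-1]
    if pi.size > 2:
        conv = np.convolve(pi, pi)
        d[2:] += gmerge * conv[: pi.size - 2]
    return d


def delta_tau(
    rates: EventRates,
    pi: np.ndarray,
    tau: np.ndarray,
    conservation_mode: str = "corrected",
    literal: bool = False,
) -> np.ndarray:
    """Expected per-event change in the count of both-homeolog r-event runs.

    A run acquires content from both homeologs when a cross-chromosome
    extension (B12, B21, C12, C21) lengthens a single-homeolog run, or when
    a merger's three parts (two runs + the bridging deletion) are not all
    on one homeolog.  ``literal=True`` reproduces the printed update
    (duplicated pB12 term and the bare r(r-1) factor) for audit.
    """
    ext = rates.pB + rates.pC
    loss = ext + 2.0 * (rates.pD + rates.pE)
    gmerge = (
        rates.pD + rates.pE
        if conservation_mode == "corrected"
        else 2.0 * (rates.pD + rates.pE)
    )
    vv = rates.by_variant
    if literal:
        cross = 2.0 * vv["pB12"] + vv["pC12"] + vv["pC21"]
    else:
        cross = rates.cross_extension
    c3 = rates.phi1**3 + rates.phi2**3

    n = pi.size
    d = np.zeros(n)
    if n >= 2:
        d[1] = cross * pi[0] - loss * pi[1] * tau[1]
    if n >= 3:
        r = np.arange(3, n + 1, dtype=np.float64)
        stay = ext * pi[1:-1] * tau[1:-1]
        if literal:
            convert = cross * pi[1:-1] * (1.0 - r * (r - 1.0))
        else:
            convert = cross * pi[1:-1] * (1.0 - tau[1:-1])
        w = pi * (1.0 - tau)
        conv = np.convolve(pi, pi)[: n - 2]
        convw = np.convolve(w, w)[: n - 2]
        merge = gmerge * (conv - c3 * convw)
        d[2:] = stay + convert + merge - loss * tau[2:] * pi[2:]
    return d


def advance(
    state: RecurrenceState,
    rates: EventRates,
    dpi: np.ndarray,
    dtau: np.ndarray,
    Lambda: float,
    config: RecurrenceConfig,
) -> RecurrenceState:
    """One macro-step of Lambda events; conserves total genes R(u_bar+v_bar)."""
    if Lambda <= 0:
        raise ValueError("Lambda must be positive")
    R = state.R
    Rp = R + Lambda * float(dpi.sum())
    if Rp <= 0:
        raise StepSizeError("run count would become non-positive; reduce Lambda")
    pi_raw = (R * state.pi + Lambda * dpi) / Rp
    u_new = (R * state.u_bar + Lambda * rates.mu_total) / Rp
    v_new = (R / Rp) * (state.u_bar + state.v_bar) - u_new
    if v_new <= 0:
        raise StepSizeError("v_bar would become non-positive; reduce Lambda")

    T = R * state.pi * state.tau
    Tp = T + Lambda * dtau
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_new = np.where(pi_raw > 0, Tp / (Rp * np.maximum(pi_raw, 1e-300)), 0.0)
    tau_new = np.clip(tau_new, 0.0, 1.0)
    tau_new[0] = 0.0

    pi_new = np.clip(pi_raw, 0.0, None)
    tot = pi_new.sum()
    if tot <= 0:
        raise StepSizeError("pi lost all mass; reduce Lambda")
    pi_new = pi_new / tot

    theta_new = v_new / (u_new + v_new)
    return RecurrenceState(
        pi=pi_new, tau=tau_new, u_bar=u_new, v_bar=v_new, theta=theta_new, R=Rp
    )


@dataclass
class RecurrenceTrajectory:
    config: RecurrenceConfig
    records: pd.DataFrame  # per step: theta, pA..p_other, u_bar, v_bar, R
    final_state: RecurrenceState
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )  # (theta, pi, tau) at requested checkpoints

    def interp(self, one_minus_theta, column: str) -> np.ndarray:
        """Linear interpolation of a recorded column on the 1-theta axis."""
        xs = 1.0 - self.records["theta"].to_numpy()
        ys = self.records[column].to_numpy()
        return np.interp(np.asarray(one_minus_theta, dtype=float), xs, ys)


def run_recurrence(
    config: RecurrenceConfig, checkpoints: Sequence[float] = ()
) -> RecurrenceTrajectory:
    """Iterate compute_rates -> deltas -> advance from theta_start to theta_stop.

    With ``Lambda=None`` the step size is adaptive: each macro-step changes
    the run count by at most 1% and theta by at most ``dtheta_max``.
    ``checkpoints`` is a decreasing sequence of theta values at which the
    full pi/tau vectors are snapshotted.
    """
    state = RecurrenceState.initial(config)
    rows = []
    snaps: list[tuple[float, np.ndarray, np.ndarray]] = []
    pending = sorted(checkpoints, reverse=True)

    def record(st: RecurrenceState, rt: EventRates):
        rows.append(
            {
                "theta": st.theta,
                "pA": rt.pA,
                "pB": rt.pB,
                "pC": rt.pC,
                "pD": rt.pD,
                "pE": rt.pE,
                "p_other": rt.p_other,
                "u_bar": st.u_bar,
                "v_bar": st.v_bar,
                "R": st.R,
                "tau_total": st.tau_total,
            }
        )

    for _ in range(config.max_steps):
        if state.theta <= config.theta_stop or state.v_bar <= 1.0 + 1e-12:
            break
        rates = compute_rates(state, config)
        dpi = delta_pi(rates, state.pi, config.conservation_mode)
        dtau = delta_tau(
            rates, state.pi, state.tau, config.conservation_mode, config.literal_tau
        )
        record(state, rates)

        if config.Lambda is not None:
            lam = config.Lambda
        else:
            sum_dpi = abs(float(dpi.sum()))
            lam1 = 0.01 * state.R / max(sum_dpi, 1e-300)
            lam2 = (
                config.dtheta_max
                * state.R
                * (state.u_bar + state.v_bar)
                / max(rates.mu_total, 1e-300)
            )
            lam = min(lam1, lam2)
        new_state = advance(state, rates, dpi, dtau, lam, config)
        if new_state.theta >= state.theta:
            raise StepSizeError(
                "theta failed to decrease (oscillation); reduce Lambda"
            )
        while pending and new_state.theta <= pending[0]:
            snaps.append((new_state.theta, new_state.pi.copy(), new_state.tau.copy()))
            pending.pop(0)
        state = new_state
    else:
        raise StepSizeError("max_steps exceeded before reaching theta_stop")

    rates = compute_rates(state, config)
    record(state, rates)
    return RecurrenceTrajectory(
        config=config,
        records=pd.DataFrame(rows),
        final_state=state,
        snapshots=snaps,
    )
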