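"""Brute-force nested-sum oracles for the event-rate formulas.

These evaluate the uncollected multiple summations exactly as displayed
(position index j inside the undeleted run, deletion length a term by
term), independent of the package's reassociated/correlation-based
implementation.  Small supports only.
"""

import numpy as np


def gamma(a: int, mu: float) -> float:
    p = 1.0 / mu
    return p * (1.0 - p) ** (a - 1)


def e_rho(rho: np.ndarray) -> float:
    return float(sum((l + 1) * rho[l] for l in range(len(rho))))


def naive_pA(rho: np.ndarray, mu: float) -> float:
    """Sum_{l>2} rho(l) Sum_{j=2}^{l-1} Sum_{a=1}^{l-j} gamma(a), over E_rho."""
    L = len(rho)
    tot = 0.0
    for l in range(3, L + 1):
        for j in range(2, l):
            for a in range(1, l - j + 1):
                tot += rho[l - 1] * gamma(a, mu)
    return tot / e_rho(rho)


def naive_muA(rho: np.ndarray, mu: float) -> float:
    L = len(rho)
    tot = 0.0
    for l in range(3, L + 1):
        for j in range(2, l):
            for a in range(1, l - j + 1):
                tot += rho[l - 1] * gamma(a, mu) * a
    return tot / e_rho(rho)


def naive_pCii(rho: np.ndarray, mu: float) -> float:
    """Sum_{l>1} Sum_{k>=1} rho(l) rho(k) Sum_{j=2}^{l} Sum_{a=l-j+1}^{l-j+k}."""
    L = len(rho)
    tot = 0.0
    for l in range(2, L + 1):
        for k in range(1, L + 1):
            for j in range(2, l + 1):
                for a in range(l - j + 1, l - j + k + 1):
                    tot += rho[l - 1] * rho[k - 1] * gamma(a, mu)
    return tot / e_rho(rho)


def naive_muCii(rho: np.ndarray, mu: float) -> float:
    L = len(rho)
    tot = 0.0
    for l in range(2, L + 1):
        for k in range(1, L + 1):
            for j in range(2, l + 1):
                for a in range(l - j + 1, l - j + k + 1):
                    tot += rho[l - 1] * rho[k - 1] * gamma(a, mu) * a
    return tot / e_rho(rho)


def naive_pDiii(rho: np.ndarray, mu: float) -> float:
    """Triple-rho form: Sum_j Sum_{a=l-j+k+1}^{l-j+k+h} gamma(a)."""
    L = len(rho)
    tot = 0.0
    for l in range(2, L + 1):
        for k in range(1, L + 1):
            for h in range(1, L + 1):
                for j in range(2, l + 1):
                    for a in range(l - j + k + 1, l - j + k + h + 1):
                        tot += rho[l - 1] * rho[k - 1] * rho[h - 1] * gamma(a, mu)
    return tot / e_rho(rho)


def naive_muDiii(rho: np.ndarray, mu: float) -> float:
    L = len(rho)
    tot = 0.0
    for l in range(2, L + 1):
        for k in range(1, L + 1):
            for h in range(1, L + 1):
                for j in range(2, l + 1):
                    for a in range(l - j + k + 1, l - j + k + h + 1):
                        tot += rho[l - 1] * rho[k - 1] * rho[h - 1] * gamma(a, mu) * a
    return tot / e_rho(rho)
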