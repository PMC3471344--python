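"""Goodness-of-fit helpers for run-length distributions.

The recurrence rests on the modeling assumption that undeleted-run lengths
are geometric (mean v_bar) and independent; these helpers quantify how well
simulated or observed run lengths conform.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["geometric_chi2_gof"]


def geometric_chi2_gof(lengths) -> tuple[float, int, float]:
    """Chi-square test of lengths on {1, 2, ...} against a geometric law.

    The success parameter is the MLE p = 1/mean.  Cells are unit bins with a
    right tail bin, pooled from the right until every expected count is at
    least 5; degrees of freedom = cells - 2 (one for the total, one for the
    estimated parameter).  Returns (statistic, df, p_value).
    """
    x = np.asarray(lengths, dtype=np.int64)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(x < 1):
        raise ValueError("lengths must be >= 1")
    n = x.size
    p = 1.0 / x.mean()
    kmax = int(x.max())
    k = np.arange(1, kmax + 1, dtype=np.float64)
    pmf = p * (1.0 - p) ** (k - 1.0)
    exp = n * np.append(pmf, (1.0 - p) ** kmax)  # unit bins + tail
    obs = np.bincount(x, minlength=kmax + 1)[1:].astype(np.float64)
    obs = np.append(obs, 0.0)
    while exp.size > 3 and exp[-1] < 5.0:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp = exp[:-1]
        obs = obs[:-1]
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = int(exp.size - 2)
    return stat, df, float(sps.chi2.sf(stat, df))
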