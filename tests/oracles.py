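"""Independent brute-force oracles used by the test and acceptance suites.

These deliberately avoid the package's own code paths: segmentation is
checked against exhaustive least-squares change-point enumeration, and
statistics against scipy/statsmodels reference implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def best_partition_rss(x: np.ndarray, n_breakpoints: int, min_seg: int = 1):
    """Exhaustive search for the ``n_breakpoints`` split minimizing RSS.

    Returns (breakpoints tuple, rss).  O(n^k) enumeration; fine for the
    small instances used in tests.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def seg_rss(a: int, b: int) -> float:
        s = prefix[b] - prefix[a]
        s2 = prefix2[b] - prefix2[a]
        return s2 - s * s / (b - a)

    best_bps: tuple[int, ...] = ()
    best = seg_rss(0, n)
    if n_breakpoints == 0:
        return best_bps, best
    for bps in itertools.combinations(range(min_seg, n - min_seg + 1), n_breakpoints):
        bounds = (0, *bps, n)
        if any(b - a < min_seg for a, b in zip(bounds, bounds[1:])):
            continue
        rss = sum(seg_rss(a, b) for a, b in zip(bounds, bounds[1:]))
        if rss < best:
            best = rss
            best_bps = bps
    return best_bps, best


def single_changepoint_ml(x: np.ndarray, min_seg: int = 1) -> int:
    """Maximum-likelihood single change-point (minimum two-segment RSS)."""
    bps, _ = best_partition_rss(x, 1, min_seg=min_seg)
    return bps[0]


def chisq_oracle(table, correction: bool = False):
    """Reference chi-square via scipy."""
    from scipy.stats import chi2_contingency

    stat, p, _, _ = chi2_contingency(np.asarray(table), correction=correction)
    return float(stat), float(p)


def logistic_oracle(X: np.ndarray, y: np.ndarray):
    """Reference logistic fit via statsmodels; returns (coefs, ses)."""
    import statsmodels.api as sm

    fit = sm.Logit(y, X).fit(disp=0)
    return np.asarray(fit.params), np.asarray(fit.bse)
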