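"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive each quantity from its definition, using none
of the package's code paths.
"""

import numpy as np


def bh_stepup_bruteforce(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up from the definition.

    Adjusted p for the k-th smallest p-value is min over k' >= k of
    p_(k') * m / k', capped at 1; rejections are all tests with
    p <= p_(k*) where k* is the largest k with p_(k) <= q k / m.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    adj_sorted = np.empty(m)
    for k in range(m):  # ranks are 1-based
        ks = np.arange(k + 1, m + 1)
        adj_sorted[k] = min(1.0, (p_sorted[k:] * m / ks).min())
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p_sorted <= thresholds)
    if passing.size:
        p_star = p_sorted[passing[-1]]
        reject = p <= p_star
    else:
        reject = np.zeros(m, dtype=bool)
    return adjusted, reject


def pooled_two_sample_t(y1: np.ndarray, y0: np.ndarray) -> float:
    """Classical pooled-variance two-sample t statistic (group1 minus group0)."""
    n1, n0 = len(y1), len(y0)
    sp2 = (((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()) / (n1 + n0 - 2)
    return (y1.mean() - y0.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
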