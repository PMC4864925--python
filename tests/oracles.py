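"""Independent from-definition oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the library
routines) they are used to check.
"""

import math
from itertools import count

import numpy as np


def poisson_upper_tail_oracle(observed: int, lam: float) -> float:
    """P(X >= observed | lam) by direct term-by-term summation in log
    space, far past the mass of the distribution."""
    if observed <= 0:
        return 1.0
    total = 0.0
    for k in count(observed):
        log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
        term = math.exp(log_term)
        total += term
        if k > lam and term < 1e-18 * max(total, 1e-300):
            break
    return min(1.0, total)


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by full enumeration of the
    hypergeometric distribution with exact integer arithmetic."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, col1)
    p = 0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > n - row1:
            continue
        p += math.comb(row1, k) * math.comb(n - row1, col1 - k)
    return p / denom


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values straight from the definition:
    adj_(i) = min_{j >= i} min(1, n * p_(j) / j) over the sorted order."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, p[order] * n / np.arange(1, n + 1))
    # enforce monotonicity from the largest rank down
    for i in range(n - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def logrank_oracle(carrier, times, events):
    """Two-group log-rank chi-square from the definition: at each distinct
    event time, a 2x2 hypergeometric contributes mean d*n1/n and variance
    d*(n1/n)*(1-n1/n)*(n-d)/(n-1) to the O-E sum."""
    carrier = np.asarray(carrier, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & carrier).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & carrier).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return float("nan"), float("nan")
    stat = o_minus_e ** 2 / var
    from scipy.stats import chi2
    return stat, float(chi2.sf(stat, 1))
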