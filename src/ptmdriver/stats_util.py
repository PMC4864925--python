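"""Small shared statistical primitives.

Every resampling test in the package reports the add-one empirical
p value (1 + #{null >= observed}) / (1 + n_shuffles), so p is never 0 and
never below 1/(n_shuffles+1).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError


def empirical_p(n_null_at_least: int, n_shuffles: int) -> float:
    """One-sided add-one empirical p value."""
    if n_shuffles < 1:
        raise DegenerateInputError("empirical p requires at least one shuffle")
    return (1.0 + n_null_at_least) / (1.0 + n_shuffles)


def poisson_upper_tail(observed: int, lam: float) -> float:
    """Exact upper-tail Poisson probability P(X >= observed | lam).

    Evaluated through the regularised incomplete gamma function (the exact
    value of the infinite sum), not a normal approximation.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_one_sided(table) -> tuple[float, float, bool]:
    """One-sided (greater) Fisher exact test on a 2x2 table.

    Returns (odds_ratio, p, continuity_corrected). The p value is the
    hypergeometric upper tail. The odds ratio is the sample odds ratio
    (a*d)/(b*c) with a 0.5 substitution in every cell only when some cell
    is zero, in which case continuity_corrected is True.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a nonnegative 2x2 array")
    a, b = t[0]
    c, d = t[1]
    corrected = bool((t == 0).any())
    if corrected:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    odds = (a_ * d_) / (b_ * c_)
    _, p = stats.fisher_exact(t.astype(int), alternative="greater")
    return float(odds), float(p), corrected
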