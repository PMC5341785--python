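"""Independent brute-force oracles used to check the statistical kernels.

Everything here is exact rational arithmetic or a direct transcription of
the textbook definition, deliberately sharing no code path with the
package implementation.
"""

from fractions import Fraction
from math import comb

import numpy as np


def binom_tail_exact(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), exact.

    Sums whichever tail has fewer terms and complements if needed.
    """
    p = Fraction(p)
    q = 1 - p
    if k <= 0:
        return Fraction(1)
    if k > n:
        return Fraction(0)

    def term(i: int) -> Fraction:
        return comb(n, i) * p ** i * q ** (n - i)

    if k <= n - k + 1:
        return 1 - sum(term(i) for i in range(k))
    return sum(term(i) for i in range(k, n + 1))


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X hypergeometric: n draws, K successes among N, exact."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return Fraction(1)
    if k > hi:
        return Fraction(0)
    denom = comb(N, n)
    if k - lo <= hi - k + 1:
        s = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, k))
        return 1 - Fraction(s, denom)
    s = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    return Fraction(s, denom)


def fisher_greater_exact(alt_t: int, depth_t: int, alt_c: int,
                         depth_c: int) -> Fraction:
    """One-sided Fisher's exact p for [[alt_t, ref_t], [alt_c, ref_c]],
    alternative: the target row is enriched for the alt column."""
    return hypergeom_sf_exact(alt_t, depth_t + depth_c, alt_t + alt_c, depth_t)


def bh_stepup_manual(pvals, q_cutoff: float = 0.05):
    """Benjamini-Hochberg by the textbook step-up rule with cummin q-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = ranked
    return q, q <= q_cutoff
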