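"""Independent oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
the Fisher oracle enumerates every table with the observed margins using
exact rational arithmetic, and the Ward oracle is the textbook merge
criterion evaluated by hand-maintained cluster statistics.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration over fixed margins.

    Sums the exact hypergeometric point probability of every table with
    the same margins whose probability is <= the observed table's
    (minimum-likelihood convention), all in exact rationals.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return Fraction(1)

    def point(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = point(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = point(x)
        if p <= p_obs:
            total += p
    return min(total, Fraction(1))
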