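"""Independent brute-force oracles used to verify the statistical kernels.

Everything here works by exact enumeration with rational arithmetic and
never calls the code paths it checks.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb


@lru_cache(maxsize=None)
def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p: sum of the probabilities of all tables
    with the observed margins whose point probability does not exceed
    the observed one (ties handled exactly via Fractions)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def pr(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pr(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        px = pr(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


def hypergeom_upper_tail(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) when drawing n_b items from a universe containing
    n_a marked items, by direct summation."""
    denom = comb(n_universe, n_b)
    total = sum(
        comb(n_a, x) * comb(n_universe - n_a, n_b - x)
        for x in range(max(k, max(0, n_a + n_b - n_universe)),
                       min(n_a, n_b) + 1)
    )
    return float(Fraction(total, denom))


def bh_step_up(pvals):
    """Benjamini-Hochberg q-values straight from the step-up definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q
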