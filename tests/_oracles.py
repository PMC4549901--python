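"""Independent oracles used across test modules (no package internals)."""

from fractions import Fraction
from math import comb


def enum_fisher(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Exact-rational Fisher p values by exhaustive hypergeometric enumeration.

    Returns (p_greater, p_less, p_two_sided) for the a-cell with margins
    fixed; two-sided by the method of small p (exact ties included).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    p_greater = sum(p for k, p in pmf.items() if k >= a)
    p_less = sum(p for k, p in pmf.items() if k <= a)
    p_two = sum(p for p in pmf.values() if p <= p_obs)
    return float(p_greater), float(p_less), float(p_two)
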