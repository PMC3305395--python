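"""Brute-force enumeration oracles for the exact tests.

Independent of the package implementation: probabilities are handled as
integer outcome weights over a common power-of-denominator scale, summed
and divided exactly at the end.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def binom_weights(n: int, num: int, den: int) -> list[int]:
    """Integer weights proportional to Binomial(n, num/den) pmf (scale den**n)."""
    return [comb(n, k) * num**k * (den - num) ** (n - k) for k in range(n + 1)]


def binom_one_tailed(k: int, n: int, num: int, den: int) -> float:
    w = binom_weights(n, num, den)
    scale = den**n
    if k * den <= n * num:
        return float(Fraction(sum(w[: k + 1]), scale))
    return float(Fraction(sum(w[k:]), scale))


def binom_two_tailed(k: int, n: int, num: int, den: int) -> float:
    w = binom_weights(n, num, den)
    total = sum(x for x in w if x <= w[k])
    return float(min(Fraction(total, den**n), Fraction(1)))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact independence p by enumerating all tables with the
    observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = comb(r1, a) * comb(r2, c)
    total = sum(w for w in weights if w <= obs)
    return float(Fraction(total, comb(n, c1)))
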