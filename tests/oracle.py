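"""Independent brute-force oracles used only by the tests.

Everything here is exact rational arithmetic (stdlib Fraction) or naive
enumeration, deliberately sharing no code path with the package.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb


def mass_exact(y: int, x: int, n1: int, n2: int) -> Fraction:
    """p(y|x) = (N2/N1)^y (x+y)!/(x! y!) (1+N2/N1)^-(x+y+1), exactly."""
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) * (1 + r) ** (-(x + y + 1))


def cumulative_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(mass_exact(i, x, n1, n2) for i in range(y + 1))


def pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided rule: 2F if F <= 1/2, else 2(1-F)."""
    f = cumulative_exact(x, y, n1, n2)
    if f <= Fraction(1, 2):
        return 2 * f
    return 2 * (1 - f)


def bh_stepup(p_values: list[float]) -> list[float]:
    """Hand-rolled Benjamini-Hochberg step-up, input order preserved."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = running
    return q


def n50_brute(lengths: list[int]) -> int:
    """Largest length l among the inputs such that bases in sequences of
    length >= l reach half the total."""
    total = sum(lengths)
    for candidate in sorted(set(lengths), reverse=True):
        if 2 * sum(v for v in lengths if v >= candidate) >= total:
            return candidate
    raise AssertionError("unreachable for non-empty input")


def rel_err(a: float, b: float) -> float:
    if b == 0:
        return abs(a)
    return abs(a - b) / abs(b)
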