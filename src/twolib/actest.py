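"""Exact two-library count statistics for no-replicate RNA-seq designs.

The Audic-Claverie test asks whether a gene's read counts in two sequencing
libraries are consistent with equal underlying expression.  Conditional on
the count ``x`` observed in library A, the count ``y`` in library B follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

where N1, N2 are the total read counts of the two libraries.  This is a
negative-binomial mass in y with x+1 "successes" and success probability
N1/(N1+N2), which is how the cumulative sums are evaluated here (via the
regularized incomplete beta function, stable in both tails).

The two-sided p-value doubles the smaller tail: with F = sum_{i<=y} p(i|x),

    p = 2 F            if F <= 0.5
    p = 2 (1 - F)      otherwise (the point mass at y stays in the lower
                       tail; the complement is the strict upper tail).

Multiple testing is controlled with Benjamini-Hochberg step-up q-values.
"""
from __future__ import annotations

import math
import numbers
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InputDomainError, InputFormatError

__all__ = [
    "LibraryPair",
    "GenePairCounts",
    "TestResult",
    "ac_probability",
    "ac_pvalue",
    "ac_pvalues",
    "bh_fdr",
    "run_ac_tests",
]

# p-values are clamped into (tiny, 1] so downstream log transforms stay finite
P_FLOOR = float(np.finfo(float).tiny)


def _check_count(value, name: str) -> int:
    if isinstance(value, (bool, np.bool_)):
        raise InputDomainError(f"{name} must be an integer count, got a bool")
    if not isinstance(value, numbers.Integral):
        # reject fractional counts rather than round: the mass function is
        # defined on integers only
        raise InputDomainError(f"{name} must be an integer count, got {value!r}")
    if value < 0:
        raise InputDomainError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class LibraryPair:
    """Total read counts of the two libraries (the test's N1 and N2)."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, numbers.Integral):
                raise InputDomainError(f"library total {name} must be an integer")
            if value < 1:
                raise InputDomainError(f"library total {name} must be >= 1, got {value}")
            object.__setattr__(self, name, int(value))

    @property
    def ratio(self) -> float:
        """N2 / N1."""
        return self.n2 / self.n1

    @property
    def success_prob(self) -> float:
        """N1 / (N1 + N2): the negative-binomial success probability."""
        return self.n1 / (self.n1 + self.n2)


@dataclass(frozen=True)
class GenePairCounts:
    """Per-gene read counts in the two conditions."""

    gene_id: str
    x: int
    y: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _check_count(self.x, "x"))
        object.__setattr__(self, "y", _check_count(self.y, "y"))


@dataclass(frozen=True)
class TestResult:
    """Outcome of the exact test for one gene.

    ``tail_mass`` is the conditional lower-tail mass F = sum_{i<=y} p(i|x),
    kept so callers can reconstruct which branch produced the p-value.
    """

    gene_id: str
    p_value: float
    q_value: float
    tail_mass: float


def ac_probability(y: int, x: int, libs: LibraryPair) -> float:
    """Conditional probability p(y | x) of observing y reads in library B.

    Evaluated in log space through the log-gamma function, so counts up to
    and beyond 1e6 neither overflow nor underflow prematurely.
    """
    y = _check_count(y, "y")
    x = _check_count(x, "x")
    log_ratio = math.log(libs.n2) - math.log(libs.n1)
    logp = (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(libs.n2 / libs.n1)
    )
    return min(math.exp(logp), 1.0)


def _tail_masses(x: np.ndarray, y: np.ndarray, libs: LibraryPair):
    """(lower tail F = P[i <= y | x], strict upper tail P[i > y | x])."""
    s = libs.success_prob
    lower = stats.nbinom.cdf(y, x + 1, s)
    upper = stats.nbinom.sf(y, x + 1, s)
    return lower, upper


def _two_sided(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    p = np.where(lower <= 0.5, 2.0 * lower, 2.0 * upper)
    return np.clip(p, P_FLOOR, 1.0)


def ac_pvalue(x: int, y: int, libs: LibraryPair) -> float:
    """Two-sided exact p-value for equal expression given counts (x, y)."""
    x = _check_count(x, "x")
    y = _check_count(y, "y")
    lower, upper = _tail_masses(np.asarray(x), np.asarray(y), libs)
    return float(_two_sided(lower, upper))


def ac_pvalues(
    x: Sequence[int], y: Sequence[int], libs: LibraryPair
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`ac_pvalue`.

    Returns ``(p_values, tail_masses)`` as float arrays.  Counts must be
    integer-typed arrays; fractional dtypes are rejected.
    """
    xa = np.asarray(x)
    ya = np.asarray(y)
    for arr, name in ((xa, "x"), (ya, "y")):
        if not np.issubdtype(arr.dtype, np.integer):
            raise InputDomainError(f"{name} counts must have an integer dtype, got {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise InputDomainError(f"{name} counts must be non-negative")
    lower, upper = _tail_masses(xa, ya, libs)
    return _two_sided(lower, upper), np.asarray(lower, dtype=float)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the p-values sorted ascending.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputDomainError("p_values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise InputDomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ac_tests(
    counts: Iterable[GenePairCounts], libs: LibraryPair
) -> list[TestResult]:
    """Run the exact test over a count table and adjust jointly for FDR."""
    records = list(counts)
    if not records:
        raise InputFormatError("empty count table")
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(g for g in ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
        raise InputFormatError(f"duplicate gene id: {dup!r}")
    x = np.array([r.x for r in records], dtype=np.int64)
    y = np.array([r.y for r in records], dtype=np.int64)
    p, tail = ac_pvalues(x, y, libs)
    q = bh_fdr(p)
    return [
        TestResult(gene_id=g, p_value=float(pi), q_value=float(qi), tail_mass=float(ti))
        for g, pi, qi, ti in zip(ids, p, q, tail)
    ]
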