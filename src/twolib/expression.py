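"""Expression quantification and differential-expression calling.

RPKM (reads per kilobase of transcript per million mapped reads) normalizes a
raw count C by transcript length L (bases) and library depth N (total
uniquely aligned reads):

    RPKM = 1e9 * C / (N * L)

Fold change between conditions is reported as log2(RPKM_b / RPKM_a); because
length cancels within a gene this equals the count ratio rescaled by N2/N1.
A gene is called differentially expressed when it clears both a q-value
cutoff (default FDR <= 0.001) and an absolute log2 ratio cutoff (default 1,
i.e. two-fold), boundary values inclusive.

Also provided: comparative-threshold-cycle (2^-ddCt) relative expression for
qRT-PCR validation data measured against an internal-control gene.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDomainError

__all__ = [
    "ExpressionRecord",
    "CtMeasurement",
    "rpkm",
    "default_rpkm_floor",
    "log2_ratio",
    "classify_deg",
    "relative_expression_ddct",
    "expression_table",
    "UP",
    "DOWN",
    "NOT_SIGNIFICANT",
]

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    length_bp: int
    rpkm_a: float
    rpkm_b: float
    log2_ratio: float


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate-averaged threshold-cycle values for one target gene.

    `ref` fields are the internal-control gene (e.g. 18S rDNA) in the same
    sample.  Values far outside the usual 5-40 cycle range trigger a warning
    but are not rejected.
    """

    gene_id: str
    ct_target_treated: float
    ct_target_control: float
    ct_ref_treated: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_target_control",
            "ct_ref_treated",
            "ct_ref_control",
        ):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise InputDomainError(f"{name} must be finite")
            if not 5.0 <= value <= 40.0:
                warnings.warn(
                    f"{name}={value} is outside the typical 5-40 cycle range",
                    stacklevel=3,
                )


def rpkm(c, n, l) -> float:
    """Reads per kilobase per million mapped reads: 1e9 * c / (n * l)."""
    if n < 1:
        raise InputDomainError(f"total mapped reads must be >= 1, got {n}")
    if l < 1:
        raise InputDomainError(f"transcript length must be >= 1, got {l}")
    if c < 0:
        raise InputDomainError(f"read count must be >= 0, got {c}")
    if c == 0:
        return 0.0
    return 1e9 * c / (n * l)


def default_rpkm_floor(length_bp: int, n_smaller: int) -> float:
    """RPKM a single read would get on this gene in the shallower library.

    Used as the zero-replacement floor for log ratios: it keeps ratios
    finite while scaling with both sequencing depth and gene length, so a
    zero count in a deep library is treated as stronger evidence of absence
    than one in a shallow library.
    """
    return rpkm(1, n_smaller, length_bp)


def log2_ratio(rpkm_b: float, rpkm_a: float, floor: float) -> float:
    """log2(rpkm_b / rpkm_a) with both values floored at `floor` (> 0)."""
    if floor <= 0:
        raise ConfigurationError(f"floor must be positive, got {floor}")
    return math.log2(max(rpkm_b, floor) / max(rpkm_a, floor))


def classify_deg(
    q: float,
    log2_ratio: float,
    fdr_cut: float = 0.001,
    lfc_cut: float = 1.0,
) -> str:
    """Call a gene up / down / not_significant under the dual threshold.

    Boundary values pass: q == fdr_cut and |log2_ratio| == lfc_cut are
    significant.
    """
    if not 0.0 <= q <= 1.0:
        raise InputDomainError(f"q-value must be in [0, 1], got {q}")
    if q <= fdr_cut and log2_ratio >= lfc_cut:
        return UP
    if q <= fdr_cut and log2_ratio <= -lfc_cut:
        return DOWN
    return NOT_SIGNIFICANT


def relative_expression_ddct(m: CtMeasurement) -> float:
    """Comparative-Ct fold change 2^-ddCt of target vs control condition."""
    ddct = (m.ct_target_treated - m.ct_ref_treated) - (
        m.ct_target_control - m.ct_ref_control
    )
    return 2.0 ** (-ddct)


def expression_table(
    counts: pd.DataFrame,
    n_a: int,
    n_b: int,
    floor: float | None = None,
) -> pd.DataFrame:
    """Vectorized RPKM + log2 ratio over a count table.

    `counts` needs columns gene_id, length, count_a, count_b.  When `floor`
    is None each gene gets the depth-aware default floor (one read in the
    shallower library at that gene's length).
    """
    required = {"gene_id", "length", "count_a", "count_b"}
    missing = required - set(counts.columns)
    if missing:
        raise InputDomainError(f"count table missing columns: {sorted(missing)}")
    if n_a < 1 or n_b < 1:
        raise InputDomainError("library totals must be >= 1")
    length = counts["length"].to_numpy(dtype=float)
    if length.size and length.min() < 1:
        raise InputDomainError("transcript lengths must be >= 1")
    rpkm_a = 1e9 * counts["count_a"].to_numpy(dtype=float) / (n_a * length)
    rpkm_b = 1e9 * counts["count_b"].to_numpy(dtype=float) / (n_b * length)
    if floor is None:
        floors = 1e9 / (min(n_a, n_b) * length)
    else:
        if floor <= 0:
            raise ConfigurationError(f"floor must be positive, got {floor}")
        floors = np.full_like(length, float(floor))
    lr = np.log2(np.maximum(rpkm_b, floors) / np.maximum(rpkm_a, floors))
    out = counts[["gene_id", "length"]].copy()
    out["rpkm_a"] = rpkm_a
    out["rpkm_b"] = rpkm_b
    out["log2_ratio"] = lr
    return out
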