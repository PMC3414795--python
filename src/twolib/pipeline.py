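"""End-to-end orchestration: count table in, DEG tables and report out.

Stages run in a fixed order — RPKM normalization, exact two-library test,
Benjamini-Hochberg adjustment, dual-threshold DEG classification — and every
run writes a log recording seeds, cutoffs and library totals so filter
attrition is auditable.  Also holds the percentage summarizer used for
annotation-rate style reporting and the Monte-Carlo calibration harness
(empirical type-I error and power of the whole pipeline on synthetic data).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rounding import percent
from .actest import LibraryPair, ac_pvalues, bh_fdr
from .errors import ConfigurationError, InputDomainError, InputFormatError
from .expression import NOT_SIGNIFICANT, classify_deg, expression_table
from .simulate import SyntheticScenario, simulate_counts

__all__ = [
    "RunConfig",
    "SummaryReport",
    "ClassCalibration",
    "CalibrationReport",
    "read_count_table",
    "write_count_table",
    "deg_table",
    "run_deg_pipeline",
    "rate_summary",
    "calibrate",
]

COUNT_COLUMNS = ("gene_id", "length", "count_a", "count_b")
RESULT_COLUMNS = (
    "gene_id",
    "length",
    "rpkm_a",
    "rpkm_b",
    "log2_ratio",
    "p_value",
    "q_value",
    "status",
)


@dataclass
class RunConfig:
    """Configuration of one differential-expression run."""

    counts_path: str | Path
    out_dir: str | Path
    fdr_cut: float = 0.001
    lfc_cut: float = 1.0
    lib_size_a: int | None = None  # None -> column sum
    lib_size_b: int | None = None
    floor: float | None = None  # None -> depth-aware default per gene
    seed: int = 0
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.fdr_cut <= 0 or self.lfc_cut <= 0:
            raise ConfigurationError("fdr_cut and lfc_cut must be positive")
        for name in ("lib_size_a", "lib_size_b"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise ConfigurationError(f"{name} must be >= 1 when given")


@dataclass
class SummaryReport:
    """Run summary; n_total is always n_up + n_down by construction."""

    n_genes: int
    n_up: int
    n_down: int
    fdr_cut: float
    lfc_cut: float
    lib_size_a: int
    lib_size_b: int
    seed: int | None = None
    stage_log: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    def to_text(self) -> str:
        lines = [
            "differential expression summary",
            f"genes tested\t{self.n_genes}",
            f"library totals\t{self.lib_size_a}\t{self.lib_size_b}",
            f"thresholds\tFDR <= {self.fdr_cut}\t|log2 ratio| >= {self.lfc_cut}",
            f"up-regulated\t{self.n_up}",
            f"down-regulated\t{self.n_down}",
            f"total DEGs\t{self.n_total}",
        ]
        if self.seed is not None:
            lines.append(f"seed\t{self.seed}")
        return "\n".join(lines) + "\n"


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Parse a TSV count table (gene_id, length, count_a, count_b).

    Lines starting with '#' are comments.  Malformed rows raise
    :class:`InputFormatError` naming the offending line number.
    """
    rows: list[tuple[str, int, int, int]] = []
    header_seen = False
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != COUNT_COLUMNS:
                    raise InputFormatError(
                        f"{path}: line {lineno}: expected header "
                        f"{' '.join(COUNT_COLUMNS)}, got {' '.join(fields)}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            gene_id = fields[0]
            try:
                length, count_a, count_b = (int(v) for v in fields[1:])
            except ValueError:
                raise InputFormatError(
                    f"{path}: line {lineno}: length and counts must be integers"
                ) from None
            if length < 1 or count_a < 0 or count_b < 0:
                raise InputFormatError(
                    f"{path}: line {lineno}: length must be >= 1 and counts >= 0"
                )
            rows.append((gene_id, length, count_a, count_b))
    if not rows:
        raise InputFormatError(f"{path}: count table has no data rows")
    df = pd.DataFrame(rows, columns=list(COUNT_COLUMNS))
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise InputFormatError(f"{path}: duplicate gene id {dup!r}")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        df.to_csv(handle, sep="\t", index=False)


def deg_table(
    counts: pd.DataFrame,
    libs: LibraryPair,
    fdr_cut: float = 0.001,
    lfc_cut: float = 1.0,
    floor: float | None = None,
) -> pd.DataFrame:
    """In-memory core of the pipeline: counts -> per-gene results.

    Returns a frame with the count, RPKM, test and classification columns.
    Genes are returned in input order; the BH adjustment internally breaks
    p-value ties by (p, gene_id) so output is reproducible.
    """
    if counts.empty:
        raise InputFormatError("empty count table")
    expr = expression_table(counts, libs.n1, libs.n2, floor=floor)
    x = counts["count_a"].to_numpy(dtype=np.int64)
    y = counts["count_b"].to_numpy(dtype=np.int64)
    p, tail = ac_pvalues(x, y, libs)
    q = bh_fdr(p)
    out = expr.copy()
    out.insert(2, "x", x)
    out.insert(3, "y", y)
    out["p_value"] = p
    out["q_value"] = q
    out["tail_mass"] = tail
    out["status"] = [
        classify_deg(qi, li, fdr_cut, lfc_cut)
        for qi, li in zip(out["q_value"], out["log2_ratio"])
    ]
    return out


def run_deg_pipeline(config: RunConfig) -> tuple[SummaryReport, pd.DataFrame]:
    """Execute the full pipeline from a count TSV and write all outputs.

    Writes to `config.out_dir`: expression.tsv (the result table),
    tests.tsv (gene_id/x/y/p/q), report.txt, run.log.
    """
    counts = read_count_table(config.counts_path)
    n_a = config.lib_size_a if config.lib_size_a is not None else int(counts["count_a"].sum())
    n_b = config.lib_size_b if config.lib_size_b is not None else int(counts["count_b"].sum())
    if n_a < 1 or n_b < 1:
        raise InputDomainError(
            "library totals must be >= 1; supply lib_size_a/lib_size_b when "
            "column sums are zero"
        )
    libs = LibraryPair(n_a, n_b)
    result = deg_table(counts, libs, config.fdr_cut, config.lfc_cut, config.floor)

    n_up = int((result["status"] == "up").sum())
    n_down = int((result["status"] == "down").sum())
    report = SummaryReport(
        n_genes=len(result),
        n_up=n_up,
        n_down=n_down,
        fdr_cut=config.fdr_cut,
        lfc_cut=config.lfc_cut,
        lib_size_a=n_a,
        lib_size_b=n_b,
        seed=config.seed,
        stage_log=[
            f"read_counts\tin=-\tout={len(counts)}",
            f"rpkm\tin={len(counts)}\tout={len(counts)}",
            f"ac_test\tin={len(counts)}\tout={len(result)}",
            f"classify\tin={len(result)}\tdeg={n_up + n_down}",
        ],
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "expression.tsv", "w") as handle:
        handle.write(f"# seed={config.seed}\n")
        result[list(RESULT_COLUMNS)].to_csv(handle, sep="\t", index=False)
    with open(out_dir / "tests.tsv", "w") as handle:
        handle.write(f"# seed={config.seed}\n")
        result[["gene_id", "x", "y", "p_value", "q_value"]].to_csv(
            handle, sep="\t", index=False
        )
    (out_dir / "report.txt").write_text(report.to_text())
    log_lines = [
        f"seed={config.seed}",
        f"counts_path={config.counts_path}",
        f"lib_size_a={n_a} lib_size_b={n_b}",
        f"fdr_cut={config.fdr_cut} lfc_cut={config.lfc_cut}",
        *report.stage_log,
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report, result


def rate_summary(
    pairs: Sequence[tuple[int, int]], decimals: int = 2
) -> list[float]:
    """Percentages 100*num/den, rounded half-up to `decimals` places."""
    out = []
    for num, den in pairs:
        if den < 1:
            raise InputDomainError(f"denominator must be >= 1, got {den}")
        if num < 0 or num > den:
            raise InputDomainError(
                f"numerator must be in [0, denominator], got {num}/{den}"
            )
        out.append(percent(num, den, decimals))
    return out


@dataclass
class ClassCalibration:
    """Detection rate of one truth class, averaged over replicates."""

    n_genes: int
    rate: float
    se: float  # NaN when n_reps == 1 (undefined)


@dataclass
class CalibrationReport:
    n_reps: int
    type_i: ClassCalibration
    power: dict[float, ClassCalibration]


def calibrate(
    scenario: SyntheticScenario,
    n_reps: int,
    seed: int = 0,
    fdr_cut: float = 0.001,
    lfc_cut: float = 1.0,
    min_mu: float = 0.0,
) -> CalibrationReport:
    """Monte-Carlo type-I error and power of the full decision rule.

    Each replicate redraws the scenario at a derived seed, runs the
    pipeline core, and scores calls against the truth table.  Power is
    reported per |log2 effect| class and counts only calls in the true
    direction; `min_mu` restricts scoring to genes whose smaller expected
    count is at least that deep (power is depth-dependent).
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]

    null_rates: list[float] = []
    power_rates: dict[float, list[float]] = {}
    n_null = 0
    n_per_class: dict[float, int] = {}
    for rep_seed in rep_seeds:
        sc = SyntheticScenario(
            **{
                **{f: getattr(scenario, f) for f in scenario.__dataclass_fields__},
                "seed": rep_seed,
            }
        )
        counts, truth = simulate_counts(sc)
        libs = LibraryPair(int(counts["count_a"].sum() or 1), int(counts["count_b"].sum() or 1))
        result = deg_table(counts, libs, fdr_cut, lfc_cut)
        called = result["status"].to_numpy()
        true_status = truth["true_status"].to_numpy()
        true_lfc = truth["true_log2fc"].to_numpy()
        depth_ok = truth["mu_a"].to_numpy() >= min_mu

        null_mask = true_status == "not_de"
        if null_mask.any():
            null_rates.append(float((called[null_mask] != NOT_SIGNIFICANT).mean()))
            n_null += int(null_mask.sum())
        for effect in sorted({abs(v) for v in true_lfc if v != 0.0}):
            mask = (np.abs(true_lfc) == effect) & depth_ok
            if not mask.any():
                continue
            correct = called[mask] == true_status[mask]
            power_rates.setdefault(effect, []).append(float(correct.mean()))
            n_per_class[effect] = n_per_class.get(effect, 0) + int(mask.sum())

    def _summarize(rates: list[float], n_genes: int) -> ClassCalibration:
        if not rates:
            return ClassCalibration(n_genes=0, rate=math.nan, se=math.nan)
        rate = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / math.sqrt(len(rates))) if len(rates) > 1 else math.nan
        return ClassCalibration(n_genes=n_genes, rate=rate, se=se)

    return CalibrationReport(
        n_reps=n_reps,
        type_i=_summarize(null_rates, n_null),
        power={e: _summarize(r, n_per_class[e]) for e, r in power_rates.items()},
    )
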