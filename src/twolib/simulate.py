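"""Seeded generators for every input the pipeline consumes.

The generators emulate a two-library elicitation experiment at desk scale:
two sequencing libraries of unequal total size, a few thousand transcripts
with log-normal baseline abundance, a differentially expressed subset with
known log2 effects (a "strong" class around 2.5 log2 and a "slight" class
around 1.25 log2, mirroring how induced pathway genes split in such
studies), Poisson count sampling, plus FASTA sets with controlled
scaffolding-gap (N) content and FASTQ reads with controlled quality and GC
composition.

The count model matches the exact test's null: given relative abundances
a_g and lengths L_g, the expected count of gene g in a library of total
size N is N * a_g L_g / sum_h a_h L_h, and observed counts are independent
Poisson draws around that expectation.  An optional gamma-Poisson
(overdispersed) mode exists to demonstrate the anti-conservativeness of a
no-replicate test on biologically variable data; it is an extension, not
the default.

Reproducibility: one root seed per generator call; independent substreams
are spawned from it with numpy's SeedSequence (order: lengths, abundance,
effect assignment, counts / record composition), so identical arguments
give byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly_qc import ReadRecord, SequenceRecord
from .errors import ConfigurationError

__all__ = [
    "SyntheticScenario",
    "simulate_counts",
    "simulate_fasta",
    "simulate_fastq",
]

# condition statuses in the truth table
TRUE_UP = "up"
TRUE_DOWN = "down"
TRUE_NULL = "not_de"


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic two-library count experiment.

    Defaults: library totals are the printed read totals of a typical
    elicitation run scaled down by 10^3 for desk-scale speed; 10% of genes
    are differentially expressed, split evenly between a strong (2.5 log2)
    and a slight (1.25 log2) effect class with random sign.
    """

    n_genes: int = 2000
    lib_size_a: int = 29460
    lib_size_b: int = 29896
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    de_fraction: float = 0.10
    lfc_classes: tuple[tuple[float, float], ...] = ((2.5, 0.5), (1.25, 0.5))
    length_log_mean: float = math.log(744.0)
    length_log_sd: float = 0.45
    min_length: int = 100
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.lib_size_a < 1 or self.lib_size_b < 1:
            raise ConfigurationError("library sizes must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1)")
        weights = [w for _, w in self.lfc_classes]
        if self.de_fraction > 0:
            if not weights or all(w == 0 for w in weights):
                raise ConfigurationError("lfc_classes has no usable weights")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigurationError("lfc_classes weights must sum to 1")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive when set")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(n)]


def simulate_counts(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a two-condition count table plus its ground-truth table.

    Returns ``(counts, truth)``: counts has columns
    gene_id/length/count_a/count_b; truth has gene_id/length_bp/
    true_log2fc/true_status/mu_a/mu_b (the Poisson expectations, useful for
    depth-stratified power analyses).
    """
    sc = scenario
    rng_len, rng_ab, rng_de, rng_cnt = _streams(sc.seed, 4)

    lengths = np.maximum(
        np.round(rng_len.lognormal(sc.length_log_mean, sc.length_log_sd, sc.n_genes)),
        sc.min_length,
    ).astype(np.int64)
    abundance = rng_ab.lognormal(sc.baseline_log_mean, sc.baseline_log_sd, sc.n_genes)

    lfc = np.zeros(sc.n_genes)
    n_de = int(round(sc.de_fraction * sc.n_genes))
    if n_de:
        de_idx = rng_de.choice(sc.n_genes, size=n_de, replace=False)
        effects = np.array([e for e, _ in sc.lfc_classes])
        weights = np.array([w for _, w in sc.lfc_classes], dtype=float)
        weights = weights / weights.sum()
        chosen = rng_de.choice(effects.size, size=n_de, p=weights)
        # exactly balanced signs: counts are compositional, so a sign
        # imbalance would shift the relative abundance of every null gene
        signs = np.ones(n_de)
        signs[: n_de // 2] = -1.0
        rng_de.shuffle(signs)
        lfc[de_idx] = effects[chosen] * signs

    # apply the effect symmetrically (x 2^(+/-lfc/2) per condition): the
    # B:A abundance ratio is still 2^lfc, but the two library compositions
    # stay exchangeable, so per-condition normalization does not bias the
    # estimated log2 ratios of null genes
    abundance_a = abundance * np.exp2(-lfc / 2.0)
    abundance_b = abundance * np.exp2(lfc / 2.0)
    weight_a = abundance_a * lengths
    weight_b = abundance_b * lengths
    mu_a = sc.lib_size_a * weight_a / weight_a.sum()
    mu_b = sc.lib_size_b * weight_b / weight_b.sum()

    if sc.dispersion is None:
        count_a = rng_cnt.poisson(mu_a)
        count_b = rng_cnt.poisson(mu_b)
    else:
        # gamma-Poisson: Var = mu + dispersion * mu^2
        shape = 1.0 / sc.dispersion
        count_a = rng_cnt.poisson(rng_cnt.gamma(shape, mu_a / shape))
        count_b = rng_cnt.poisson(rng_cnt.gamma(shape, mu_b / shape))

    gene_ids = [f"gene{idx:05d}" for idx in range(sc.n_genes)]
    counts = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length": lengths,
            "count_a": count_a.astype(np.int64),
            "count_b": count_b.astype(np.int64),
        }
    )
    status = np.where(lfc > 0, TRUE_UP, np.where(lfc < 0, TRUE_DOWN, TRUE_NULL))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths,
            "true_log2fc": lfc,
            "true_status": status,
            "mu_a": mu_a,
            "mu_b": mu_b,
        }
    )
    return counts, truth


def simulate_fasta(
    n: int,
    length_log_mean: float = math.log(744.0),
    length_log_sd: float = 0.45,
    min_length: int = 100,
    gap_ok_weight: float = 0.85,
    gap_threshold: float = 0.05,
    gap_max: float = 0.30,
    seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Assembled sequences with controlled N-gap content, plus truth.

    A fraction `gap_ok_weight` of records draw their gap ratio uniformly in
    [0, gap_threshold) ("ok" scaffolds), the rest in [gap_threshold,
    gap_max).  The truth table records both the intended class and the
    realized (integer-rounded) gap ratio of each record.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0.0 <= gap_ok_weight <= 1.0:
        raise ConfigurationError("gap_ok_weight must be in [0, 1]")
    if not 0.0 < gap_threshold <= gap_max <= 1.0:
        raise ConfigurationError("need 0 < gap_threshold <= gap_max <= 1")
    rng_len, rng_gap, rng_seq = _streams(seed, 3)
    lengths = np.maximum(
        np.round(rng_len.lognormal(length_log_mean, length_log_sd, n)), min_length
    ).astype(np.int64)
    ok = rng_gap.random(n) < gap_ok_weight
    target = np.where(
        ok,
        rng_gap.uniform(0.0, gap_threshold, n),
        rng_gap.uniform(gap_threshold, gap_max, n),
    )
    records: list[SequenceRecord] = []
    realized = np.empty(n)
    bases = np.array(list("ACGT"))
    for idx in range(n):
        length = int(lengths[idx])
        n_gap = int(np.floor(target[idx] * length))
        seq = rng_seq.choice(bases, size=length)
        if n_gap:
            # place the N run in the interior, like a scaffolding gap
            start = int(rng_seq.integers(1, max(length - n_gap, 2)))
            seq[start : start + n_gap] = "N"
        realized[idx] = n_gap / length
        records.append(SequenceRecord(seq_id=f"seq{idx:05d}", sequence="".join(seq)))
    truth = pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in records],
            "length": lengths,
            "gap_ratio": realized,
            "gap_ok": realized < gap_threshold,
        }
    )
    return records, truth


def simulate_fastq(
    n_reads: int,
    read_length: int = 100,
    q20_target: float = 0.9385,
    gc_target: float = 0.4569,
    n_rate: float = 0.0001,
    phred_offset: int = 33,
    seed: int = 0,
) -> list[ReadRecord]:
    """Reads whose per-base stats hit the requested targets in expectation.

    Each base independently has P(Q >= 20) = `q20_target` (high-quality
    scores uniform on 20..40, low on 2..19), P(G or C) = `gc_target` and
    P(N) = `n_rate`; A/T share the remainder equally.
    """
    if n_reads < 1 or read_length < 1:
        raise ConfigurationError("n_reads and read_length must be >= 1")
    for name, value in (("q20_target", q20_target), ("gc_target", gc_target), ("n_rate", n_rate)):
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
    if gc_target + n_rate > 1.0:
        raise ConfigurationError("gc_target + n_rate must not exceed 1")
    if phred_offset not in (33, 64):
        raise ConfigurationError(f"phred_offset must be 33 or 64, got {phred_offset}")
    rng_q, rng_b = _streams(seed, 2)
    at = (1.0 - gc_target - n_rate) / 2.0
    probs = [at, gc_target / 2.0, gc_target / 2.0, at, n_rate]
    alphabet = np.array(list("ACGTN"))
    reads: list[ReadRecord] = []
    for idx in range(n_reads):
        high = rng_q.random(read_length) < q20_target
        quals = np.where(
            high,
            rng_q.integers(20, 41, read_length),
            rng_q.integers(2, 20, read_length),
        )
        seq = rng_b.choice(alphabet, size=read_length, p=probs)
        reads.append(
            ReadRecord(
                read_id=f"read{idx:06d}",
                sequence="".join(seq),
                qualities=tuple(int(q) for q in quals),
            )
        )
    return reads
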