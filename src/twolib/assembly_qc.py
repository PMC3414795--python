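"""Sequence-set statistics for de novo transcriptome assemblies and reads.

Covers the numbers a short-read assembly report typically prints: N50,
length-bin distributions, gap ratios of scaffolded sequences (runs of N
inserted between joined contigs), and per-base FASTQ quality/composition
summaries (Q20 percentage, N percentage, GC percentage).

Conventions
-----------
* N50: sort lengths descending and accumulate; the N50 is the first length
  at which the running sum reaches half the total bases, so sequences of
  length >= N50 always hold at least 50% of assembled bases.
* Q20: a base counts as high quality when its Phred score is >= 20 (the
  standard convention); pass ``strict_greater=True`` for a literal > 20.
* GC: N bases are excluded from the numerator but stay in the denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._rounding import percent
from .errors import InputDomainError, InputFormatError

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "AssemblyStats",
    "n50",
    "gap_ratio",
    "gap_ok_fraction",
    "fastq_stats",
    "length_bins",
    "proportion_at_least",
    "assembly_stats",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """An assembled sequence (contig/scaffold/unigene) over {A,C,G,T,N}."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputDomainError(f"sequence {self.seq_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with decoded per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise InputFormatError(
                f"read {self.read_id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise InputDomainError(f"read {self.read_id!r} has negative quality scores")


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bases: int
    n50: int
    mean_length: float
    bin_counts: dict[tuple[float, float], int] = field(default_factory=dict)
    gap_ok_fraction: float = 1.0


def n50(lengths: Sequence[int]) -> int:
    """Length-weighted median sequence length.

    The returned value is always one of the input lengths, and sequences of
    that length or longer contain at least half of all bases.
    """
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise InputDomainError("n50 of an empty length list is undefined")
    if arr.min() < 1:
        raise InputDomainError("sequence lengths must be positive")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    idx = int(np.searchsorted(cum, cum[-1] / 2, side="left"))
    return int(desc[idx])


def gap_ratio(record: SequenceRecord | str) -> float:
    """Fraction of N characters (scaffolding gaps) in a sequence."""
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if not seq:
        raise InputDomainError("gap_ratio of an empty sequence is undefined")
    seq = seq.upper()
    return seq.count("N") / len(seq)


def gap_ok_fraction(records: Iterable[SequenceRecord | str], threshold: float = 0.05) -> float:
    """Proportion of sequences whose gap ratio is strictly below `threshold`."""
    ratios = [gap_ratio(r) for r in records]
    if not ratios:
        raise InputDomainError("gap_ok_fraction of an empty record set is undefined")
    return sum(r < threshold for r in ratios) / len(ratios)


def fastq_stats(
    reads: Iterable[ReadRecord],
    q_threshold: int = 20,
    strict_greater: bool = False,
) -> tuple[float, float, float]:
    """(q20_pct, n_pct, gc_pct) over all bases of a read set, unrounded.

    q20_pct counts bases with quality >= `q_threshold` (or strictly > when
    `strict_greater`); n_pct counts N bases; gc_pct counts G/C bases — N is
    excluded from the GC numerator but included in every denominator.
    """
    total = hi = n_bases = gc = 0
    for read in reads:
        quals = np.asarray(read.qualities)
        total += quals.size
        hi += int((quals > q_threshold).sum() if strict_greater else (quals >= q_threshold).sum())
        seq = read.sequence.upper()
        n_bases += seq.count("N")
        gc += seq.count("G") + seq.count("C")
    if total == 0:
        raise InputDomainError("fastq_stats of an empty read set is undefined")
    return 100.0 * hi / total, 100.0 * n_bases / total, 100.0 * gc / total


def length_bins(
    lengths: Sequence[int], bin_edges: Sequence[float]
) -> dict[tuple[float, float], int]:
    """Counts of lengths in half-open bins [e_i, e_{i+1})."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise InputDomainError("bin edges must be strictly increasing with >= 2 values")
    arr = np.asarray(lengths, dtype=float)
    counts, _ = np.histogram(arr, bins=edges)
    # np.histogram closes the last bin; re-open it to keep [e,e') semantics
    counts[-1] -= int(np.sum(arr == edges[-1]))
    return {
        (float(lo), float(hi)): int(c)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts)
    }


def proportion_at_least(
    lengths: Sequence[int], cutoff: float, decimals: int = 2
) -> float:
    """Percentage of sequences with length > cutoff, printed half-up."""
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise InputDomainError("empty length list")
    return percent(int((arr > cutoff).sum()), int(arr.size), decimals)


def assembly_stats(
    records: Sequence[SequenceRecord],
    bin_edges: Sequence[float] = (0, 100, 200, 500, 1000, 2000, float("inf")),
    gap_threshold: float = 0.05,
) -> AssemblyStats:
    """Full summary block for one assembly tier (contigs/scaffolds/unigenes)."""
    if not records:
        raise InputDomainError("empty record set")
    lengths = [len(r) for r in records]
    return AssemblyStats(
        n_sequences=len(records),
        total_bases=int(sum(lengths)),
        n50=n50(lengths),
        mean_length=float(np.mean(lengths)),
        bin_counts=length_bins(lengths, bin_edges),
        gap_ok_fraction=gap_ok_fraction(records, gap_threshold),
    )


def _validate_alphabet(seq_id: str, sequence: str, strict: bool) -> None:
    bad = set(sequence.upper()) - _ALPHABET
    if bad and strict:
        raise InputFormatError(
            f"sequence {seq_id!r} contains characters outside ACGTN: {sorted(bad)}"
        )


def read_fasta(path, strict: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Non-ACGTN characters (lowercase is normalized first) are rejected in
    strict mode and passed through otherwise; downstream GC/N counters treat
    them as non-GC, non-N.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_alphabet(rec.id, seq, strict)
        out.append(SequenceRecord(seq_id=rec.id, sequence=seq))
    if not out:
        raise InputFormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = (
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


_FASTQ_FORMATS = {33: "fastq", 64: "fastq-illumina"}


def read_fastq(path, phred_offset: int = 33) -> list[ReadRecord]:
    """Read 4-line FASTQ records, decoding qualities at the given offset."""
    try:
        fmt = _FASTQ_FORMATS[phred_offset]
    except KeyError:
        raise InputDomainError(f"phred_offset must be 33 or 64, got {phred_offset}")
    out = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            out.append(
                ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise InputFormatError(
            f"could not decode FASTQ qualities at Phred offset {phred_offset}: {exc}"
        ) from exc
    if not out:
        raise InputFormatError(f"no FASTQ records found in {path}")
    return out


def write_fastq(reads: Iterable[ReadRecord], path, phred_offset: int = 33) -> None:
    try:
        fmt = _FASTQ_FORMATS[phred_offset]
    except KeyError:
        raise InputDomainError(f"phred_offset must be 33 or 64, got {phred_offset}")
    bio = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        bio.append(rec)
    SeqIO.write(bio, str(path), fmt)
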