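"""Sequencing-data quality metrics and NUMT-removal read retention.

Implements the QC surface of the platform comparison: the fraction of
low-quality reads (mean Phred < 30), pooled read GC content, the
exact-duplicate rate (identical sequence copies in the raw data), the
clean-data proportion in bases, the mitochondrial mapping rate, and the
NUMT-contamination filter that keeps only read pairs properly and uniquely
mapped to the mitochondrial genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConsistencyError, EmptyInputError, UndefinedValueError
from .samio import AlignedPair, SequencedRead

Q30 = 30.0


@dataclass(frozen=True)
class QCReport:
    q30_read_fraction: float     # reads with mean Phred >= 30
    mean_read_gc: float
    duplication_rate: float
    clean_fraction: float
    mapping_rate: float

    def to_dict(self) -> dict:
        return asdict(self)


def q30_metrics(reads: list[SequencedRead]) -> tuple[float, np.ndarray]:
    """Low-quality read fraction and the per-position mean quality series.

    A read is low-quality iff its mean Phred is below 30 (reads, not bases,
    are classified, matching how trimming discards whole reads).  The series
    has one entry per read position up to the longest read; shorter reads
    simply stop contributing.
    """
    if not reads:
        raise EmptyInputError("q30_metrics needs at least one read")
    n_low = sum(1 for r in reads if r.mean_quality < Q30)
    max_len = max(len(r.sequence) for r in reads)
    sums = np.zeros(max_len)
    counts = np.zeros(max_len, dtype=np.int64)
    for r in reads:
        q = r.qualities
        sums[: len(q)] += q
        counts[: len(q)] += 1
    return n_low / len(reads), sums / counts


def read_gc(reads: list[SequencedRead]) -> float:
    """Pooled GC fraction over all unambiguous read bases."""
    if not reads:
        raise EmptyInputError("read_gc needs at least one read")
    gc = acgt = 0
    for r in reads:
        c = Counter(r.sequence)
        gc += c["G"] + c["C"]
        acgt += c["A"] + c["C"] + c["G"] + c["T"]
    if acgt == 0:
        raise UndefinedValueError("no unambiguous bases in input reads")
    return gc / acgt


def _pair_key(pair) -> str:
    # order-sensitive concatenation: mate 1 then mate 2
    if isinstance(pair, AlignedPair):
        return pair.seq1 + "\x00" + pair.seq2
    s1, s2 = pair
    return s1 + "\x00" + s2


def exact_duplicate_rate(pairs) -> tuple[float, Counter]:
    """Exact-duplicate rate over read pairs, by identical sequence copies.

    Pairs are grouped by the concatenation of both mates' sequences
    (mate 1 then mate 2; orientation-sensitive, no coordinates involved).
    One member of each group is the original; the rest are duplicates:
    rate = (total - number_of_groups) / total.  Also returns the multiset of
    group sizes.
    """
    pairs = list(pairs)
    if not pairs:
        raise EmptyInputError("exact_duplicate_rate needs at least one pair")
    groups = Counter(_pair_key(p) for p in pairs)
    cluster_sizes = Counter(groups.values())
    return (len(pairs) - len(groups)) / len(pairs), cluster_sizes


def dedup_pairs(pairs: list[AlignedPair]) -> list[AlignedPair]:
    """Keep the first member of every exact-duplicate group, preserving order."""
    seen: set[str] = set()
    out = []
    for p in pairs:
        k = _pair_key(p)
        if k not in seen:
            seen.add(k)
            out.append(p)
    return out


def clean_fraction(raw_reads: list[SequencedRead], retained_reads: list[SequencedRead]) -> float:
    """Clean-data proportion, measured in bases.

    ``retained_reads`` must be a subset of ``raw_reads`` by (read_id, mate);
    the fraction is retained base count over raw base count, reflecting that
    trimming may shorten a retained read.
    """
    raw_ids = {(r.read_id, r.mate_index): len(r.sequence) for r in raw_reads}
    retained_bases = 0
    for r in retained_reads:
        key = (r.read_id, r.mate_index)
        if key not in raw_ids:
            raise ConsistencyError(f"retained read {key} not present in raw set")
        if len(r.sequence) > raw_ids[key]:
            raise ConsistencyError(f"retained read {key} longer than its raw read")
        retained_bases += len(r.sequence)
    raw_bases = sum(raw_ids.values())
    if raw_bases == 0:
        raise EmptyInputError("raw read set has no bases")
    return retained_bases / raw_bases


def retain_mito_pairs(pairs: list[AlignedPair], mito_ref_name: str) -> list[AlignedPair]:
    """NUMT-removal retention rule: keep pairs properly and uniquely mapped
    to the mitochondrial genome; order preserved."""
    return [
        p for p in pairs
        if p.ref_name == mito_ref_name and p.properly_paired and p.unique
    ]


def mapping_rate(pairs: list[AlignedPair], mito_ref_name: str) -> float:
    """Fraction of pairs mapped to the mitochondrial reference."""
    if not pairs:
        raise EmptyInputError("mapping_rate needs at least one pair")
    return sum(p.ref_name == mito_ref_name for p in pairs) / len(pairs)


def qc_report(
    raw_reads: list[SequencedRead],
    retained_reads: list[SequencedRead],
    pairs: list[AlignedPair],
    mito_ref_name: str,
) -> QCReport:
    low_fraction, _ = q30_metrics(raw_reads)
    dup_rate, _ = exact_duplicate_rate(pairs)
    return QCReport(
        q30_read_fraction=1.0 - low_fraction,
        mean_read_gc=read_gc(raw_reads),
        duplication_rate=dup_rate,
        clean_fraction=clean_fraction(raw_reads, retained_reads),
        mapping_rate=mapping_rate(pairs, mito_ref_name),
    )
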