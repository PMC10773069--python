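"""Read-pair container and SAM / FASTQ round-tripping (via pysam).

A sequenced fragment appears downstream as an :class:`AlignedPair`: both
mates' coordinates, strands, sequences and qualities, plus the pairing and
uniqueness flags that drive NUMT-contamination removal.  The package's own
simulator emits ungapped alignments (CIGAR one match run), and the pileup /
coverage code requires that shape; gapped records are rejected rather than
silently miscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pysam

from .errors import EmptyInputError, MalformedAlignmentError

#: Mapping quality at or above which an alignment counts as uniquely mapped
#: (bwa-mem convention; secondary/supplementary records are never unique).
UNIQUE_MAPQ = 30


@dataclass(frozen=True)
class SequencedRead:
    """One raw read: id, mate index (1 or 2), bases and Phred qualities."""

    read_id: str
    mate_index: int
    sequence: str
    qualities: np.ndarray  # uint8 Phred scores, one per base

    def __post_init__(self):
        q = np.asarray(self.qualities, dtype=np.uint8)
        if len(q) != len(self.sequence):
            raise MalformedAlignmentError(
                f"{self.read_id}/{self.mate_index}: quality length "
                f"{len(q)} != sequence length {len(self.sequence)}"
            )
        if q.size and q.max() > 93:
            raise MalformedAlignmentError("Phred scores must be in [0, 93]")
        object.__setattr__(self, "qualities", q)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities))


@dataclass(frozen=True)
class AlignedPair:
    """One fragment as an aligned, ungapped read pair (1-based coordinates)."""

    read_id: str
    ref_name: str
    pos1: int
    pos2: int
    strand1: str
    strand2: str
    properly_paired: bool
    unique: bool
    mapq: int
    insert_size: int  # signed, SAM TLEN convention; abs() is fragment length
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray

    @property
    def fragment_length(self) -> int:
        return abs(self.insert_size)

    @property
    def fragment_start(self) -> int:
        return min(self.pos1, self.pos2)

    @property
    def fragment_end(self) -> int:
        return self.fragment_start + self.fragment_length - 1

    @property
    def aligned_bases(self) -> int:
        return len(self.seq1) + len(self.seq2)

    def reads(self) -> tuple[SequencedRead, SequencedRead]:
        return (
            SequencedRead(self.read_id, 1, self.seq1, self.qual1),
            SequencedRead(self.read_id, 2, self.seq2, self.qual2),
        )

    def with_flags(self, properly_paired=None, unique=None) -> "AlignedPair":
        kw = {}
        if properly_paired is not None:
            kw["properly_paired"] = properly_paired
        if unique is not None:
            kw["unique"] = unique
            kw["mapq"] = self.mapq if unique else 0
        return replace(self, **kw)


def _flag(mate: int, strand: str, mate_strand: str, proper: bool) -> int:
    f = 0x1 | (0x40 if mate == 1 else 0x80)
    if proper:
        f |= 0x2
    if strand == "-":
        f |= 0x10
    if mate_strand == "-":
        f |= 0x20
    return f


def write_sam(pairs: list[AlignedPair], path, ref_name: str, ref_length: int) -> None:
    """Write pairs as coordinate-unsorted SAM with mandatory columns.

    Uniqueness is encoded purely in MAPQ (0 for non-unique, the pair's MAPQ
    otherwise); the properly-paired state in flag bit 0x2.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for mate, pos, strand, mstrand, mpos, seq, qual in (
                (1, p.pos1, p.strand1, p.strand2, p.pos2, p.seq1, p.qual1),
                (2, p.pos2, p.strand2, p.strand1, p.pos1, p.seq2, p.qual2),
            ):
                a = pysam.AlignedSegment()
                a.query_name = p.read_id
                a.flag = _flag(mate, strand, mstrand, p.properly_paired)
                a.reference_id = 0
                a.reference_start = pos - 1
                a.mapping_quality = p.mapq if p.unique else 0
                a.cigarstring = f"{len(seq)}M"
                a.next_reference_id = 0
                a.next_reference_start = mpos - 1
                tlen = p.insert_size
                a.template_length = tlen if mate == 1 else -tlen
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in qual)
                )
                out.write(a)


def read_sam(path) -> tuple[list[AlignedPair], dict[str, int]]:
    """Read a SAM of ungapped pairs back into AlignedPair records.

    Returns the pairs plus the reference-length dictionary from the header.
    Records whose CIGAR is not a single match run (M/=/X) raise
    MalformedAlignmentError; unpaired leftovers are dropped.
    """
    first: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None or len(rec.cigartuples) != 1 or rec.cigartuples[0][0] not in (0, 7, 8):
                raise MalformedAlignmentError(
                    f"{rec.query_name}: only ungapped alignments are supported "
                    f"(CIGAR {rec.cigarstring})"
                )
            other = first.pop(rec.query_name, None)
            if other is None:
                first[rec.query_name] = rec
                continue
            r1, r2 = (other, rec) if other.is_read1 else (rec, other)
            pairs.append(
                AlignedPair(
                    read_id=r1.query_name,
                    ref_name=r1.reference_name,
                    pos1=r1.reference_start + 1,
                    pos2=r2.reference_start + 1,
                    strand1="-" if r1.is_reverse else "+",
                    strand2="-" if r2.is_reverse else "+",
                    properly_paired=r1.is_proper_pair,
                    unique=r1.mapping_quality >= UNIQUE_MAPQ,
                    mapq=r1.mapping_quality,
                    insert_size=r1.template_length,
                    seq1=r1.query_sequence,
                    seq2=r2.query_sequence,
                    qual1=np.asarray(r1.query_qualities, dtype=np.uint8),
                    qual2=np.asarray(r2.query_qualities, dtype=np.uint8),
                )
            )
    return pairs, ref_lengths


def write_fastq(pairs: list[AlignedPair], path_r1, path_r2) -> None:
    """Export raw reads (R1/R2) in sequencing orientation.

    Reverse-strand mates are stored reference-oriented in SAM; here they are
    reverse-complemented back to the orientation the sequencer emitted.
    """
    from .reference import reverse_complement

    if not pairs:
        raise EmptyInputError("no pairs to export")
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            for fh, seq, qual, strand, mate in (
                (f1, p.seq1, p.qual1, p.strand1, 1),
                (f2, p.seq2, p.qual2, p.strand2, 2),
            ):
                if strand == "-":
                    seq = reverse_complement(seq)
                    qual = qual[::-1]
                qstr = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{p.read_id}/{mate}\n{seq}\n+\n{qstr}\n")
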