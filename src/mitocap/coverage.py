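"""Per-base depth, x1-million relative coverage, and depth concordance.

The comparison surface for sequencing depth works on *relative* coverage:
each position's depth divided by the total depth of the whole mitochondrial
genome, multiplied by one million, so profiles from runs of different yield
are directly comparable.  For RNA data the same normalization is applied per
strand (light / heavy), with a fragment assigned to the strand its
first-in-pair read maps to.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import (
    CoordinateError,
    EmptyInputError,
    InvalidParameterError,
    UndefinedValueError,
)
from .samio import AlignedPair

MILLION = 1_000_000.0


class StrandMode(str, Enum):
    BOTH = "both"
    LIGHT = "light"   # fragment's first-in-pair read on the forward strand
    HEAVY = "heavy"   # first-in-pair read on the reverse strand


@dataclass(frozen=True)
class DepthProfile:
    """Per-position read-base depth over a 1-based reference."""

    ref_length: int
    depths: np.ndarray
    strand: StrandMode = StrandMode.BOTH

    def __post_init__(self):
        d = np.asarray(self.depths)
        if len(d) != self.ref_length:
            raise InvalidParameterError("depth array length != ref_length")
        if (d < 0).any():
            raise InvalidParameterError("depths must be non-negative")
        object.__setattr__(self, "depths", d)

    @property
    def total(self) -> float:
        return float(self.depths.sum())

    @property
    def mean(self) -> float:
        return self.total / self.ref_length


@dataclass(frozen=True)
class RelativeProfile:
    """Depth profile normalized to sum to one million."""

    ref_length: int
    values: np.ndarray


def per_base_depth(
    pairs: list[AlignedPair],
    ref_length: int,
    strand_mode: StrandMode | str = StrandMode.BOTH,
) -> DepthProfile:
    """Count read bases covering each reference position.

    Overlapping mates are both counted (no overlap correction, the samtools
    depth default); alignments are ungapped, so each read covers the closed
    interval [pos, pos + len - 1].  In light/heavy mode only reads of
    fragments assigned to that strand contribute.
    """
    strand_mode = StrandMode(strand_mode)
    # difference-array accumulation, then cumulative sum
    diff = np.zeros(ref_length + 1, dtype=np.int64)
    for p in pairs:
        if strand_mode is StrandMode.LIGHT and p.strand1 != "+":
            continue
        if strand_mode is StrandMode.HEAVY and p.strand1 != "-":
            continue
        for pos, seq in ((p.pos1, p.seq1), (p.pos2, p.seq2)):
            end = pos + len(seq) - 1
            if pos < 1 or end > ref_length:
                raise CoordinateError(
                    f"{p.read_id}: read [{pos}, {end}] outside [1, {ref_length}]"
                )
            diff[pos - 1] += 1
            diff[end] -= 1
    depths = np.cumsum(diff[:-1])
    return DepthProfile(ref_length=ref_length, depths=depths, strand=strand_mode)


def normalize_relative(profile: DepthProfile) -> RelativeProfile:
    """Relative coverage: depth / total genome depth * 1e6."""
    total = profile.total
    if total <= 0:
        raise UndefinedValueError("cannot normalize an all-zero depth profile")
    return RelativeProfile(
        ref_length=profile.ref_length,
        values=profile.depths / total * MILLION,
    )


def depth_correlation(a: RelativeProfile, b: RelativeProfile) -> float:
    """Pearson correlation of two relative-coverage profiles over positions."""
    if a.ref_length != b.ref_length:
        raise InvalidParameterError("profiles have different reference lengths")
    va, vb = np.asarray(a.values, float), np.asarray(b.values, float)
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedValueError("Pearson r undefined for zero-variance profile")
    return float(np.corrcoef(va, vb)[0, 1])


def depth_per_gb(mean_depth: float, total_sequenced_bases: float) -> float:
    """Mean mtDNA depth obtained per gigabase of raw sequencing output."""
    if total_sequenced_bases <= 0:
        raise InvalidParameterError("total_sequenced_bases must be positive")
    if mean_depth < 0:
        raise InvalidParameterError("mean_depth must be non-negative")
    return mean_depth / (total_sequenced_bases / 1e9)


def mean_depth(profile: DepthProfile) -> float:
    """Mean coverage over the whole genome (zero-depth positions included)."""
    if profile.ref_length <= 0:
        raise EmptyInputError("empty profile")
    return profile.mean
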