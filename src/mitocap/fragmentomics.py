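"""cf-mtDNA fragmentomics: size distributions, 5'-end bases and end motifs.

Fragment lengths come from alignment template lengths (not read lengths).
Each double-stranded fragment has two 5' ends — the top strand's at the
left coordinate and the bottom strand's at the right coordinate — and by
default both are counted.  End motifs are the k-mers starting at each 5'
end; their observed frequencies are normalized by the expected k-mer
composition of the (circular) mitochondrial reference, so a value of 1
means no enrichment over the reference background.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError
from .reference import BASES, ReferenceGenome, reverse_complement
from .samio import AlignedPair

#: cf-mtDNA long-fragment threshold (bp) used in the size-distribution summary.
LONG_FRAGMENT_THRESHOLD = 158


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: closed 1-based coordinates, length, 5'-end calls."""

    start: int
    end: int
    length: int
    five_prime_bases: tuple[str, str]   # (left/top-strand end, right/bottom-strand end)
    five_prime_motifs: tuple[str, str]  # k-mers in 5'->3' sequencing orientation


@dataclass(frozen=True)
class EndProportions:
    """Proportions of A/T/G/C 5'-end fragments; exact rationals, sum to 1."""

    p_A: Fraction
    p_T: Fraction
    p_G: Fraction
    p_C: Fraction

    def as_dict(self) -> dict[str, float]:
        return {b: float(getattr(self, f"p_{b}")) for b in "ATGC"}


@dataclass(frozen=True)
class SizeDistribution:
    """Normalized fragment-length histogram with its cumulative curve."""

    lengths: np.ndarray      # sorted unique integer lengths
    frequency: np.ndarray    # sums to 1
    cumulative: np.ndarray   # non-decreasing, ends at 1
    n_fragments: int

    def fraction_above(self, threshold: int = LONG_FRAGMENT_THRESHOLD) -> float:
        """Fraction of fragments strictly longer than ``threshold`` bp."""
        return float(self.frequency[self.lengths > threshold].sum())


def extract_fragments(
    pairs: list[AlignedPair],
    ref: ReferenceGenome,
    k: int = 4,
    orientation: str = "sequenced",
    ends: str = "both",
) -> tuple[list[FragmentRecord], int]:
    """Fragment lengths and 5'-end bases/motifs from retained pairs.

    ``orientation='sequenced'`` reads end bases from the read sequences
    themselves (so sequencing errors propagate realistically);
    ``'reference'`` reads them from the reference.  ``ends='both'`` records
    both 5' ends per fragment, ``'first'`` only the forward-strand end.
    Pairs with zero or coordinate-inconsistent template length are skipped;
    the skip count is returned alongside the records.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if orientation not in ("sequenced", "reference"):
        raise InvalidParameterError("orientation must be 'sequenced' or 'reference'")
    if ends not in ("both", "first"):
        raise InvalidParameterError("ends must be 'both' or 'first'")
    records: list[FragmentRecord] = []
    skipped = 0
    for p in pairs:
        length = p.fragment_length
        start = p.fragment_start
        end = start + length - 1
        if length == 0 or end > len(ref) or length < max(len(p.seq1), len(p.seq2)):
            skipped += 1
            continue
        if orientation == "reference":
            left_motif = ref.slice(start, min(start + k - 1, len(ref)))
            right_motif = reverse_complement(ref.slice(max(end - k + 1, 1), end))
        else:
            # forward mate starts at the left 5' end; reverse mate's stored
            # (reference-oriented) sequence ends at the right 5' end
            fwd_seq, rev_seq = (
                (p.seq1, p.seq2) if p.strand1 == "+" else (p.seq2, p.seq1)
            )
            left_motif = fwd_seq[:k]
            right_motif = reverse_complement(rev_seq[-k:])
        if ends == "both":
            bases = (left_motif[0], right_motif[0])
            motifs = (left_motif, right_motif)
        else:
            bases = (left_motif[0],)
            motifs = (left_motif,)
        records.append(
            FragmentRecord(
                start=start, end=end, length=length,
                five_prime_bases=tuple(bases), five_prime_motifs=tuple(motifs),
            )
        )
    return records, skipped


def size_distribution(fragments: list[FragmentRecord]) -> SizeDistribution:
    """Normalized histogram and cumulative frequency curve of fragment lengths."""
    if not fragments:
        raise EmptyInputError("size_distribution needs at least one fragment")
    lengths = np.array(sorted(Counter(f.length for f in fragments)))
    counts = Counter(f.length for f in fragments)
    freq = np.array([counts[l] for l in lengths], dtype=float)
    freq /= freq.sum()
    return SizeDistribution(
        lengths=lengths,
        frequency=freq,
        cumulative=np.cumsum(freq),
        n_fragments=len(fragments),
    )


def end_base_proportions(fragments: list[FragmentRecord]) -> EndProportions:
    """A/T/G/C-end proportions: each recorded 5' end contributes one count.

    Proportions are specific-end counts over the total of A-, T-, G- and
    C-end counts, computed as exact rationals; ambiguous terminal bases are
    excluded from numerator and denominator.
    """
    if not fragments:
        raise EmptyInputError("end_base_proportions needs at least one fragment")
    counts = Counter(
        b for f in fragments for b in f.five_prime_bases if b in BASES
    )
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise EmptyInputError("no unambiguous 5'-end bases")
    return EndProportions(
        p_A=Fraction(counts["A"], total),
        p_T=Fraction(counts["T"], total),
        p_G=Fraction(counts["G"], total),
        p_C=Fraction(counts["C"], total),
    )


def normalized_end_motifs(
    fragments: list[FragmentRecord],
    ref: ReferenceGenome,
    k: int = 4,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Observed 5'-end motif frequencies normalized by reference composition.

    Expected frequencies come from circular k-mer enumeration of the
    reference; with ``both_strands`` (the right choice when both fragment
    ends are counted) both the sequence and its reverse complement are
    enumerated.  Returns a DataFrame indexed by motif with columns
    observed, expected, normalized; normalized = observed / expected, 1
    meaning no enrichment.  Motifs with ambiguous bases are excluded.
    """
    if not fragments:
        raise EmptyInputError("normalized_end_motifs needs at least one fragment")
    observed = Counter(
        m for f in fragments for m in f.five_prime_motifs
        if len(m) == k and "N" not in m
    )
    total = sum(observed.values())
    if total == 0:
        raise EmptyInputError("no unambiguous end motifs of the requested length")
    expected = ref.kmer_composition(k, both_strands=both_strands)
    motifs = sorted(set(observed) | set(expected))
    rows = []
    for m in motifs:
        obs = observed.get(m, 0) / total
        exp = expected.get(m, 0.0)
        rows.append(
            (m, obs, exp, obs / exp if exp > 0 else np.nan)
        )
    return pd.DataFrame(
        rows, columns=["motif", "observed", "expected", "normalized"]
    ).set_index("motif")
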