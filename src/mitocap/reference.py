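"""Mitochondrial reference sequences and composition statistics.

The human mitochondrial genome is a circular molecule of 16,569 sites
(rCRS coordinate space, 1-based).  All downstream coordinates, pileups and
motif expectations in this package are defined against a
:class:`ReferenceGenome`.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pyfaidx

from .errors import CoordinateError, InvalidParameterError

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Length of the rCRS (revised Cambridge Reference Sequence, NC_012920).
RCRS_LENGTH = 16_569


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """A (by default circular) mitochondrial reference sequence.

    Positions reported anywhere in this package are 1-based and satisfy
    ``1 <= pos <= len(ref)``.
    """

    name: str
    sequence: str
    circular: bool = True
    _codes: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise InvalidParameterError("reference sequence must be non-empty")
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise InvalidParameterError(f"reference contains non-ACGTN symbols: {bad}")
        object.__setattr__(self, "sequence", seq)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        object.__setattr__(self, "_codes", codes)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self):
            raise CoordinateError(f"position {pos} outside [1, {len(self)}]")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise CoordinateError(f"interval [{start}, {end}] outside [1, {len(self)}]")
        return self.sequence[start - 1 : end]

    @property
    def codes(self) -> np.ndarray:
        """Sequence as uint8 ASCII codes (read-only view)."""
        return self._codes

    def gc_content(self) -> float:
        """GC fraction over unambiguous bases.

        The rCRS sits near 0.44, the figure usually quoted for human mtDNA.
        """
        c = Counter(self.sequence)
        acgt = sum(c[b] for b in BASES)
        return (c["G"] + c["C"]) / acgt

    def base_composition(self) -> dict[str, float]:
        """Fraction of each unambiguous base."""
        c = Counter(self.sequence)
        total = sum(c[b] for b in BASES)
        return {b: c[b] / total for b in BASES}

    def kmer_composition(self, k: int, both_strands: bool = False) -> dict[str, float]:
        """Expected k-mer frequencies by circular enumeration of the reference.

        Every one of the ``len(ref)`` starting positions contributes one k-mer
        (wrapping around the origin, since the molecule is circular).  With
        ``both_strands`` the reverse complement is enumerated as well, which is
        the correct expectation when both 5' ends of double-stranded fragments
        are counted.  K-mers containing ambiguous bases are skipped; returned
        frequencies sum to 1.
        """
        if k < 1:
            raise InvalidParameterError("k must be >= 1")
        seqs = [self.sequence]
        if both_strands:
            seqs.append(reverse_complement(self.sequence))
        counts: Counter[str] = Counter()
        for seq in seqs:
            ext = seq + seq[: k - 1] if self.circular else seq
            limit = len(seq) if self.circular else len(seq) - k + 1
            for i in range(limit):
                kmer = ext[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
        total = sum(counts.values())
        return {kmer: n / total for kmer, n in counts.items()}


def make_reference(length: int, gc_target: float, seed: int, name: str = "chrM") -> ReferenceGenome:
    """Generate a random circular reference with a prescribed GC fraction.

    The base multiset is fixed exactly (``round(gc_target * length)`` G+C,
    split as evenly as possible between G and C, likewise A/T) and then
    shuffled, so the realized GC fraction is within 1/length of the target
    and the output is deterministic under ``seed``.
    """
    if length < 1000:
        raise InvalidParameterError("reference length must be >= 1000")
    if not 0.0 < gc_target < 1.0:
        raise InvalidParameterError("gc_target must lie in (0, 1)")
    n_gc = round(gc_target * length)
    n_at = length - n_gc
    bases = np.array(
        [_BASE_TO_CODE["G"]] * (n_gc // 2)
        + [_BASE_TO_CODE["C"]] * (n_gc - n_gc // 2)
        + [_BASE_TO_CODE["A"]] * (n_at // 2)
        + [_BASE_TO_CODE["T"]] * (n_at - n_at // 2),
        dtype=np.int64,
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(bases)
    seq = "".join(BASES[i] for i in bases)
    return ReferenceGenome(name=name, sequence=seq, circular=True)


def load_fasta(path, name: str | None = None, circular: bool = True) -> ReferenceGenome:
    """Load a single-record FASTA as a ReferenceGenome (via pyfaidx)."""
    fa = pyfaidx.Fasta(str(path), as_raw=True)
    keys = list(fa.keys())
    key = name if name is not None else keys[0]
    return ReferenceGenome(name=key, sequence=str(fa[key][:]), circular=circular)


def write_fasta(ref: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref), width):
            fh.write(ref.sequence[i : i + width] + "\n")


def rcrs_fixture() -> ReferenceGenome:
    """Bundled rCRS-like fixture.

    A synthetic stand-in for NC_012920: same length (16,569) and same exact
    base composition as the rCRS (GC = 44.36%), with base order randomized.
    Composition-level statistics (GC content, length, base frequencies) match
    the real reference; locus-level sequence does not.
    """
    with importlib.resources.as_file(
        importlib.resources.files("mitocap.data") / "rcrs_synthetic.fa"
    ) as p:
        with open(p) as fh:
            lines = fh.read().splitlines()
    name = lines[0][1:].split()[0]
    seq = "".join(lines[1:])
    return ReferenceGenome(name=name, sequence=seq, circular=True)
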