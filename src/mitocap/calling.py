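"""Strand-resolved pileup, depth matching, and the heteroplasmy filter cascade.

A candidate substitution at a site is emitted as a call iff all five rules
hold:

1. at least ``min_alt_per_strand`` reads support the alternative allele on
   the forward strand AND on the reverse strand (default 3);
2. total site coverage is at least ``min_site_depth`` (default 100X);
3. the variant allele fraction is at least ``min_vaf_per_strand`` on each
   strand separately (default 2%);
4. the position is not in the blacklist of mitochondrial repeat regions
   (66-71, 303-316, 513-525, 5892, 3106-3107, 12418-12425, 16182-16194);
5. the substitution is not a C>A / G>T transversion with overall VAF at or
   below ``oxog_vaf_max`` (default 10%), the 8-oxoguanine artifact signature.

The heteroplasmy level of a call is the number of variant reads divided by
the number of total reads at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoordinateError,
    InvalidParameterError,
    MalformedAlignmentError,
)
from .reference import BASES, ReferenceGenome
from .samio import AlignedPair

_ASCII_TO_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ASCII_TO_CODE[ord(_b)] = _i

#: Base-quality floor for pileup inclusion (samtools mpileup default).
MIN_BASE_QUALITY = 13

#: rCRS repeat-region intervals excluded from calling (1-based, closed).
DEFAULT_BLACKLIST_INTERVALS = (
    (66, 71), (303, 316), (513, 525), (5892, 5892),
    (3106, 3107), (12418, 12425), (16182, 16194),
)

RULE_MIN_ALT = "min_alt_per_strand"
RULE_MIN_DEPTH = "min_site_depth"
RULE_MIN_VAF = "min_vaf_per_strand"
RULE_BLACKLIST = "blacklist"
RULE_OXOG = "oxog"
ALL_RULES = (RULE_MIN_ALT, RULE_MIN_DEPTH, RULE_MIN_VAF, RULE_BLACKLIST, RULE_OXOG)


def expand_intervals(intervals) -> frozenset[int]:
    """Expand 1-based closed intervals into the set of covered positions."""
    return frozenset(
        pos for start, end in intervals for pos in range(start, end + 1)
    )


def load_blacklist_bed(path) -> frozenset[int]:
    """Read a BED blacklist (0-based half-open) into 1-based closed positions."""
    positions: set[int] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            start0, end0 = int(fields[1]), int(fields[2])
            positions.update(range(start0 + 1, end0 + 1))
    return frozenset(positions)


@dataclass(frozen=True)
class FilterConfig:
    min_alt_per_strand: int = 3
    min_site_depth: int = 100
    min_vaf_per_strand: float = 0.02
    blacklist: frozenset[int] = field(
        default_factory=lambda: expand_intervals(DEFAULT_BLACKLIST_INTERVALS)
    )
    oxog_vaf_max: float = 0.10

    def __post_init__(self):
        if self.min_alt_per_strand < 0 or self.min_site_depth < 0:
            raise InvalidParameterError("count thresholds must be non-negative")
        if self.min_vaf_per_strand < 0 or self.oxog_vaf_max < 0:
            raise InvalidParameterError("VAF thresholds must be non-negative")
        object.__setattr__(self, "blacklist", frozenset(self.blacklist))


@dataclass(frozen=True)
class PileupSite:
    """Strand-resolved allele counts at one reference position.

    ``counts`` is a 4x2 array: rows A,C,G,T; columns forward, reverse.
    """

    position: int
    ref_base: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4, 2):
            raise InvalidParameterError("counts must have shape (4, 2)")
        if (c < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def count(self, base: str, strand: str) -> int:
        return int(self.counts[BASES.index(base), 0 if strand == "+" else 1])


class Pileup:
    """Array-backed pileup over a whole reference (positions 1..L)."""

    def __init__(self, ref: ReferenceGenome, counts: np.ndarray):
        if counts.shape != (len(ref), 4, 2):
            raise InvalidParameterError("counts must have shape (L, 4, 2)")
        self.ref = ref
        self.counts = counts

    def site(self, position: int) -> PileupSite:
        return PileupSite(
            position=position,
            ref_base=self.ref.base(position),
            counts=self.counts[position - 1],
        )

    def sites(self) -> list[PileupSite]:
        """PileupSites for every covered position, ascending."""
        covered = np.nonzero(self.counts.sum(axis=(1, 2)))[0]
        return [self.site(int(i) + 1) for i in covered]

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))


def build_pileup(
    pairs: list[AlignedPair],
    ref: ReferenceGenome,
    min_base_quality: int = MIN_BASE_QUALITY,
) -> Pileup:
    """Strand-resolved pileup from ungapped aligned pairs.

    The strand of each contributing base is its read's mapped strand; bases
    below the quality floor and ambiguous bases are excluded.  Callers are
    expected to have applied NUMT retention and deduplication upstream.
    """
    L = len(ref)
    by_len: dict[int, list] = {}
    for p in pairs:
        for pos, strand, seq, qual in (
            (p.pos1, p.strand1, p.seq1, p.qual1),
            (p.pos2, p.strand2, p.seq2, p.qual2),
        ):
            if len(qual) != len(seq):
                raise MalformedAlignmentError(
                    f"{p.read_id}: sequence/quality length mismatch"
                )
            if pos < 1 or pos + len(seq) - 1 > L:
                raise CoordinateError(
                    f"{p.read_id}: read at {pos} (+{len(seq)}) outside reference"
                )
            by_len.setdefault(len(seq), []).append((pos, strand, seq, qual))

    flat_counts = np.zeros(L * 8, dtype=np.int64)
    for rl, items in by_len.items():
        starts = np.fromiter((it[0] for it in items), dtype=np.int64, count=len(items))
        strands = np.fromiter(
            ((0 if it[1] == "+" else 1) for it in items), dtype=np.int64, count=len(items)
        )
        seq_mat = np.frombuffer(
            b"".join(it[2].encode() for it in items), dtype=np.uint8
        ).reshape(len(items), rl)
        qual_mat = np.stack([np.asarray(it[3], dtype=np.uint8) for it in items])
        codes = _ASCII_TO_CODE[seq_mat].astype(np.int64)
        pos_mat = (starts - 1)[:, None] + np.arange(rl)
        valid = (codes >= 0) & (qual_mat >= min_base_quality)
        flat = (pos_mat * 8 + codes * 2 + strands[:, None])[valid]
        flat_counts += np.bincount(flat, minlength=L * 8)
    return Pileup(ref, flat_counts.reshape(L, 4, 2))


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref_base: str
    alt_base: str
    alt_fwd: int
    alt_rev: int
    depth: int
    vaf: float
    vaf_fwd: float
    vaf_rev: float
    heteroplasmy: float
    filters_passed: tuple[str, ...] = ALL_RULES

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt_base)

    @property
    def substitution(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


def _as_arrays(sites_or_pileup):
    if isinstance(sites_or_pileup, Pileup):
        pu = sites_or_pileup
        positions = np.arange(1, len(pu.ref) + 1, dtype=np.int64)
        ref_codes = _ASCII_TO_CODE[pu.ref.codes].astype(np.int64)
        return positions, ref_codes, pu.counts
    sites = list(sites_or_pileup)
    positions = np.array([s.position for s in sites], dtype=np.int64)
    ref_codes = np.array(
        [_ASCII_TO_CODE[ord(s.ref_base)] for s in sites], dtype=np.int64
    )
    counts = (
        np.stack([s.counts for s in sites])
        if sites else np.zeros((0, 4, 2), dtype=np.int64)
    )
    return positions, ref_codes, counts


def call_variants(
    sites, cfg: FilterConfig = FilterConfig(), audit: list | None = None
) -> list[VariantCall]:
    """Apply the five-rule cascade to strand-resolved sites.

    ``sites`` may be a :class:`Pileup` or an iterable of :class:`PileupSite`.
    Each alternative base at each site is evaluated independently, so a
    multi-allelic position may yield several calls.  Sites failing filters
    are silently excluded; pass an ``audit`` list to receive
    ``(position, alt_base, failed_rules)`` tuples for every rejected
    candidate with any alt support.

    Calls are returned sorted by (position, alt base).
    """
    positions, ref_codes, counts = _as_arrays(sites)
    if len(positions) == 0:
        return []
    fwd, rev = counts[:, :, 0], counts[:, :, 1]
    depth = counts.sum(axis=(1, 2))
    fwd_depth, rev_depth = fwd.sum(axis=1), rev.sum(axis=1)
    if cfg.blacklist:
        blacklisted = np.isin(positions, np.fromiter(cfg.blacklist, dtype=np.int64))
    else:
        blacklisted = np.zeros(len(positions), dtype=bool)

    calls: list[VariantCall] = []
    for b, alt in enumerate(BASES):
        alt_fwd, alt_rev = fwd[:, b], rev[:, b]
        candidate = (ref_codes != b) & (ref_codes >= 0) & (alt_fwd + alt_rev > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf_fwd = np.where(fwd_depth > 0, alt_fwd / np.maximum(fwd_depth, 1), 0.0)
            vaf_rev = np.where(rev_depth > 0, alt_rev / np.maximum(rev_depth, 1), 0.0)
            vaf = np.where(depth > 0, (alt_fwd + alt_rev) / np.maximum(depth, 1), 0.0)
        r1 = (alt_fwd >= cfg.min_alt_per_strand) & (alt_rev >= cfg.min_alt_per_strand)
        r2 = depth >= cfg.min_site_depth
        r3 = (vaf_fwd >= cfg.min_vaf_per_strand) & (vaf_rev >= cfg.min_vaf_per_strand)
        r4 = ~blacklisted
        is_oxog_type = (ref_codes == BASES.index("C")) & (b == BASES.index("A"))
        is_oxog_type |= (ref_codes == BASES.index("G")) & (b == BASES.index("T"))
        r5 = ~(is_oxog_type & (vaf <= cfg.oxog_vaf_max))
        passed = candidate & r1 & r2 & r3 & r4 & r5
        for i in np.nonzero(passed)[0]:
            calls.append(
                VariantCall(
                    position=int(positions[i]),
                    ref_base=BASES[ref_codes[i]],
                    alt_base=alt,
                    alt_fwd=int(alt_fwd[i]),
                    alt_rev=int(alt_rev[i]),
                    depth=int(depth[i]),
                    vaf=float(vaf[i]),
                    vaf_fwd=float(vaf_fwd[i]),
                    vaf_rev=float(vaf_rev[i]),
                    heteroplasmy=float(vaf[i]),
                )
            )
        if audit is not None:
            for i in np.nonzero(candidate & ~passed)[0]:
                failed = [
                    rule for rule, ok in zip(
                        ALL_RULES, (r1[i], r2[i], r3[i], r4[i], r5[i])
                    ) if not ok
                ]
                audit.append((int(positions[i]), alt, failed))
    calls.sort(key=lambda c: c.key)
    return calls


def downsample_pairs(
    pairs: list[AlignedPair],
    target_mean_depth: float,
    ref_length: int,
    seed: int,
) -> list[AlignedPair]:
    """Depth matching: keep each pair independently with p = target / current.

    Whole pairs are kept or dropped (never single mates); if the target is at
    or above the current mean depth the input is returned unchanged.  Seeded
    and reproducible.
    """
    if target_mean_depth <= 0:
        raise InvalidParameterError("target_mean_depth must be positive")
    current = sum(p.aligned_bases for p in pairs) / ref_length
    if current <= target_mean_depth:
        return list(pairs)
    p_keep = target_mean_depth / current
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < p_keep
    return [p for p, k in zip(pairs, keep) if k]


#: The 12 strand-aware substitution types, canonical order.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)


def substitution_spectrum(calls: list[VariantCall]) -> dict[str, int]:
    """Counts of each of the 12 ref>alt substitution categories."""
    spectrum = {s: 0 for s in SUBSTITUTION_TYPES}
    for c in calls:
        spectrum[c.substitution] += 1
    return spectrum


@dataclass(frozen=True)
class CallsetComparison:
    shared: tuple
    a_only: tuple
    b_only: tuple
    spectrum_a: dict
    spectrum_b: dict
    spectrum_a_only: dict
    spectrum_b_only: dict
    mutation_density_a: float  # calls per kb of mitochondrial genome
    mutation_density_b: float


def compare_callsets(
    a: list[VariantCall], b: list[VariantCall], ref_length: int
) -> CallsetComparison:
    """Partition two callsets into shared and platform-derived calls.

    Calls are keyed by (position, alt base).  Mutation density is calls per
    kilobase of mitochondrial genome.
    """
    if ref_length <= 0:
        raise InvalidParameterError("ref_length must be positive")
    a_by, b_by = {c.key: c for c in a}, {c.key: c for c in b}
    shared_keys = sorted(a_by.keys() & b_by.keys())
    a_only_keys = sorted(a_by.keys() - b_by.keys())
    b_only_keys = sorted(b_by.keys() - a_by.keys())
    kb = ref_length / 1000.0
    return CallsetComparison(
        shared=tuple(shared_keys),
        a_only=tuple(a_only_keys),
        b_only=tuple(b_only_keys),
        spectrum_a=substitution_spectrum(a),
        spectrum_b=substitution_spectrum(b),
        spectrum_a_only=substitution_spectrum([a_by[k] for k in a_only_keys]),
        spectrum_b_only=substitution_spectrum([b_by[k] for k in b_only_keys]),
        mutation_density_a=len(a) / kb,
        mutation_density_b=len(b) / kb,
    )
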