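"""Seeded simulation of capture-based mtDNA sequencing data.

The generator emits already-aligned read pairs (SAM form): positions are
known by construction, so no aligner sits in the test loop.  It reproduces
the statistical structure the downstream analysis assumes:

* paired-end reads of fixed length (default 150 bp) from a circular
  reference, with fragments never spanning the origin;
* fragment lengths from a mixture of truncated normals, so the mass above
  any size threshold (e.g. the 158 bp cf-mtDNA cut) has a closed form;
* 5'-end base-composition bias at both fragment ends;
* heteroplasmic variants planted read-by-read at a given VAF, with the alt
  support split across strands by a controllable strand balance;
* exact duplicates (byte-identical sequence copies), and "NUMT-like"
  contaminant pairs flagged improperly paired or non-uniquely mapped;
* substitution-only sequencing errors and a two-level Phred quality model.

Every planted quantity is recorded in a :class:`Manifest` so tests can
compare downstream estimates against ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .reference import BASES, ReferenceGenome
from .samio import AlignedPair

_CODE = {b: i for i, b in enumerate(BASES)}
_ASCII_TO_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _CODE.items():
    _ASCII_TO_CODE[ord(_b)] = _i
_CODE_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class TruthVariant:
    """A planted heteroplasmy: position (1-based), alleles, VAF, strand balance."""

    position: int
    ref_base: str
    alt_base: str
    vaf: float
    strand_balance: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.vaf <= 1.0:
            raise InvalidParameterError("vaf must lie in (0, 1]")
        if not 0.0 <= self.strand_balance <= 1.0:
            raise InvalidParameterError("strand_balance must lie in [0, 1]")
        if self.alt_base == self.ref_base:
            raise InvalidParameterError("alt_base must differ from ref_base")
        for b in (self.ref_base, self.alt_base):
            if b not in _CODE:
                raise InvalidParameterError(f"allele {b!r} not in {BASES}")


@dataclass(frozen=True)
class SizeComponent:
    mean: float
    sd: float
    weight: float


#: Default cf-mtDNA-like size model: a dominant mononucleosomal peak near
#: 166 bp plus a minor long-fragment component, so a nontrivial fraction of
#: mass sits above the 158 bp threshold.
DEFAULT_SIZE_MODEL = (
    SizeComponent(166.0, 20.0, 0.85),
    SizeComponent(320.0, 40.0, 0.15),
)

#: Size model emulating solid-sample libraries built from 300-500 bp
#: sonicated fragments.
TISSUE_SIZE_MODEL = (SizeComponent(400.0, 50.0, 1.0),)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated sequencing run.

    ``end_bias`` maps each base to a relative propensity of being the
    5'-terminal base of a fragment end (both ends); uniform by default.
    ``quality_low_fraction`` of reads get constant Phred
    ``quality_low_phred`` instead of ``quality_phred`` (exercises Q30 QC).
    """

    n_fragments: int
    read_length: int = 150
    size_model: tuple[SizeComponent, ...] = DEFAULT_SIZE_MODEL
    end_bias: dict = field(default_factory=lambda: {b: 1.0 for b in BASES})
    duplicate_rate: float = 0.0
    contaminant_rate: float = 0.0
    base_error_rate: float = 0.0
    quality_phred: int = 37
    quality_low_phred: int = 25
    quality_low_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments < 1:
            raise InvalidParameterError("n_fragments must be >= 1")
        if self.read_length < 20:
            raise InvalidParameterError("read_length must be >= 20")
        for name in ("duplicate_rate", "contaminant_rate", "base_error_rate",
                     "quality_low_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        w = sum(c.weight for c in self.size_model)
        if abs(w - 1.0) > 1e-9:
            raise InvalidParameterError(f"size-model weights sum to {w}, not 1")
        if any(v < 0 for v in self.end_bias.values()) or not any(self.end_bias.values()):
            raise InvalidParameterError("end_bias propensities must be >= 0, not all 0")


@dataclass
class Manifest:
    """Ground truth of one simulated run: everything the generator planted."""

    n_pairs: int
    n_unique_fragments: int
    n_duplicates: int
    n_contaminant_pairs: int
    n_improper: int
    n_nonunique: int
    n_clean_unique: int          # unique fragments, properly paired & unique
    n_clean_pairs: int           # clean pairs among all emitted (incl. dup copies)
    total_raw_bases: int
    mean_depth_clean: float      # over clean unique fragments
    clean_fragment_lengths: np.ndarray
    end_base_counts: dict        # pooled 5'-end bases of clean unique fragments
    variants: list[dict]         # realized per-variant bookkeeping
    duplicate_sources: np.ndarray

    @property
    def duplicate_fraction(self) -> float:
        return self.n_duplicates / self.n_pairs


@dataclass
class SimulatedDataset:
    pairs: list[AlignedPair]
    manifest: Manifest
    ref: ReferenceGenome
    config: SimulationConfig

    def write_sam(self, path) -> None:
        from .samio import write_sam

        write_sam(self.pairs, path, self.ref.name, len(self.ref))

    def write_fastq(self, path_r1, path_r2) -> None:
        from .samio import write_fastq

        write_fastq(self.pairs, path_r1, path_r2)


def analytic_tail_mass(
    size_model, threshold: float, lower: float, upper: float
) -> float:
    """P(length > threshold) under the truncated-normal mixture.

    ``lower``/``upper`` are the truncation bounds the sampler enforces
    (read length and reference length).  Lengths are rounded to integers, so
    callers comparing against integer data should pass ``threshold + 0.5``.
    """
    mass = 0.0
    for c in size_model:
        a, b = (lower - c.mean) / c.sd, (upper - c.mean) / c.sd
        mass += c.weight * stats.truncnorm.sf(threshold, a, b, loc=c.mean, scale=c.sd)
    return float(mass)


def _sample_lengths(rng, cfg: SimulationConfig, n: int, upper: int) -> np.ndarray:
    comp = rng.choice(
        len(cfg.size_model), size=n, p=[c.weight for c in cfg.size_model]
    )
    lengths = np.empty(n, dtype=np.int64)
    lower = cfg.read_length
    for i, c in enumerate(cfg.size_model):
        idx = np.nonzero(comp == i)[0]
        if idx.size == 0:
            continue
        a, b = (lower - c.mean) / c.sd, (upper - c.mean) / c.sd
        draws = stats.truncnorm.rvs(
            a, b, loc=c.mean, scale=c.sd, size=idx.size, random_state=rng
        )
        lengths[idx] = np.clip(np.rint(draws).astype(np.int64), lower, upper)
    return lengths


def _sample_starts(
    rng, ref_codes: np.ndarray, cfg: SimulationConfig, lengths: np.ndarray
) -> np.ndarray:
    """Fragment starts (1-based), uniform over valid placements, reweighted by
    end_bias at both 5'-terminal bases via rejection sampling.

    The left 5' end is the reference base at ``start``; the right 5' end is
    the complement of the reference base at ``end`` (the bottom strand's
    terminal base).  Fragments never span the circular origin.
    """
    L = len(ref_codes)
    n = len(lengths)
    max_start0 = L - lengths  # 0-based inclusive upper bound
    bias = np.array([cfg.end_bias.get(b, 0.0) for b in BASES], dtype=float)
    uniform = np.allclose(bias, bias[0])
    starts0 = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    wmax = bias.max() ** 2
    while pending.size:
        prop = (rng.random(pending.size) * (max_start0[pending] + 1)).astype(np.int64)
        if uniform:
            starts0[pending] = prop
            break
        left = ref_codes[prop]
        right = 3 - ref_codes[prop + lengths[pending] - 1]  # complement code
        w = bias[left] * bias[right]
        accept = rng.random(pending.size) * wmax < w
        starts0[pending[accept]] = prop[accept]
        pending = pending[~accept]
    return starts0 + 1


def simulate_dataset(
    ref: ReferenceGenome,
    truth: list[TruthVariant] | tuple[TruthVariant, ...],
    cfg: SimulationConfig,
) -> SimulatedDataset:
    """Generate aligned pairs plus a ground-truth manifest.

    Deterministic under ``cfg.seed``: the same call yields byte-identical SAM
    records and an identical manifest.
    """
    if "N" in ref.sequence:
        raise InvalidParameterError(
            "simulation requires an N-free reference (use make_reference "
            "or the bundled synthetic fixture)"
        )
    L = len(ref)
    rl = cfg.read_length
    if L < 2 * rl:
        raise InvalidParameterError("reference shorter than two read lengths")
    for tv in truth:
        if not 1 <= tv.position <= L:
            raise InvalidParameterError(f"truth position {tv.position} outside reference")
        if ref.base(tv.position) != tv.ref_base:
            raise InvalidParameterError(
                f"truth ref_base {tv.ref_base} != reference {ref.base(tv.position)} "
                f"at {tv.position}"
            )

    rng = np.random.default_rng(cfg.seed)
    ref_codes = _ASCII_TO_CODE[ref.codes].astype(np.int64)

    n_total = cfg.n_fragments
    n_dup = int(round(cfg.duplicate_rate * n_total))
    n_unique = n_total - n_dup
    if n_unique < 1:
        raise InvalidParameterError("duplicate_rate leaves no unique fragments")

    lengths = _sample_lengths(rng, cfg, n_unique, L)
    starts = _sample_starts(rng, ref_codes, cfg, lengths)  # 1-based
    # unique fragments get distinct (start, length) placements, so planted
    # exact duplicates are the only byte-identical copies in the output
    for _ in range(200):
        key = starts * (L + 1) + lengths
        _, first_idx = np.unique(key, return_index=True)
        colliding = np.setdiff1d(np.arange(n_unique), first_idx)
        if colliding.size == 0:
            break
        lengths[colliding] = _sample_lengths(rng, cfg, colliding.size, L)
        starts[colliding] = _sample_starts(
            rng, ref_codes, cfg, lengths[colliding]
        )
    ends = starts + lengths - 1

    # read windows: left mate maps forward from start, right mate reverse
    # ending at the fragment end
    offs = np.arange(rl)
    left_idx = (starts - 1)[:, None] + offs
    right_idx = (ends - rl)[:, None] + offs
    left_codes = ref_codes[left_idx]
    right_codes = ref_codes[right_idx]

    # substitution-only sequencing errors, uniform over read bases
    if cfg.base_error_rate > 0:
        for mat in (left_codes, right_codes):
            mask = rng.random(mat.shape) < cfg.base_error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            mat[mask] = (mat[mask] + shift[mask]) % 4

    # contaminant flags on unique fragments (NUMT-like pairs)
    contaminant = rng.random(n_unique) < cfg.contaminant_rate
    kind_nonunique = rng.random(n_unique) < 0.5  # else improperly paired
    improper = contaminant & ~kind_nonunique
    nonunique = contaminant & kind_nonunique
    clean = ~contaminant

    # plant heteroplasmies read-by-read; realized counts bookkept over the
    # clean unique fragments (what survives NUMT removal and deduplication)
    variant_records = []
    for tv in truth:
        alt_code = _CODE[tv.alt_base]
        p_fwd = min(1.0, 2.0 * tv.vaf * tv.strand_balance)
        p_rev = min(1.0, 2.0 * tv.vaf * (1.0 - tv.strand_balance))
        rec = {
            "position": tv.position, "ref_base": tv.ref_base,
            "alt_base": tv.alt_base, "vaf": tv.vaf,
            "strand_balance": tv.strand_balance,
        }
        for mat, frag_lo, p, tag in (
            (left_codes, starts, p_fwd, "fwd"),
            (right_codes, ends - rl + 1, p_rev, "rev"),
        ):
            cov = (tv.position >= frag_lo) & (tv.position <= frag_lo + rl - 1)
            rows = np.nonzero(cov)[0]
            col = tv.position - frag_lo[rows]
            is_alt = rng.random(rows.size) < p
            mat[rows[is_alt], col[is_alt]] = alt_code
            clean_rows = clean[rows]
            rec[f"cov_{tag}"] = int(clean_rows.sum())
            rec[f"alt_{tag}"] = int((is_alt & clean_rows).sum())
        rec["covered"] = rec["cov_fwd"] + rec["cov_rev"] > 0
        variant_records.append(rec)

    # two-level constant quality model
    low1 = rng.random(n_unique) < cfg.quality_low_fraction
    low2 = rng.random(n_unique) < cfg.quality_low_fraction
    q_hi = np.full(rl, cfg.quality_phred, dtype=np.uint8)
    q_lo = np.full(rl, cfg.quality_low_phred, dtype=np.uint8)

    # which mate is first-in-pair: coin flip per fragment
    r1_is_forward = rng.random(n_unique) < 0.5

    left_seqs = [bytes(_CODE_TO_ASCII[row]).decode() for row in left_codes]
    right_seqs = [bytes(_CODE_TO_ASCII[row]).decode() for row in right_codes]

    pairs: list[AlignedPair] = []
    for i in range(n_unique):
        fwd = (int(starts[i]), "+", left_seqs[i], q_lo if low1[i] else q_hi)
        rev = (int(ends[i]) - rl + 1, "-", right_seqs[i], q_lo if low2[i] else q_hi)
        m1, m2 = (fwd, rev) if r1_is_forward[i] else (rev, fwd)
        tlen = int(lengths[i]) if r1_is_forward[i] else -int(lengths[i])
        pairs.append(
            AlignedPair(
                read_id=f"frag{i:07d}",
                ref_name=ref.name,
                pos1=m1[0], pos2=m2[0],
                strand1=m1[1], strand2=m2[1],
                properly_paired=not improper[i],
                unique=not nonunique[i],
                mapq=0 if nonunique[i] else 60,
                insert_size=tlen,
                seq1=m1[2], seq2=m2[2],
                qual1=m1[3], qual2=m2[3],
            )
        )

    # exact duplicates: byte-identical copies of randomly chosen originals
    dup_src = rng.integers(0, n_unique, size=n_dup)
    for j, src in enumerate(dup_src):
        p = pairs[src]
        pairs.append(
            AlignedPair(
                read_id=f"frag{n_unique + j:07d}",
                ref_name=p.ref_name, pos1=p.pos1, pos2=p.pos2,
                strand1=p.strand1, strand2=p.strand2,
                properly_paired=p.properly_paired, unique=p.unique,
                mapq=p.mapq, insert_size=p.insert_size,
                seq1=p.seq1, seq2=p.seq2, qual1=p.qual1, qual2=p.qual2,
            )
        )

    # manifest bookkeeping
    clean_lengths = lengths[clean]
    left5 = ref_codes[starts - 1]
    right5 = 3 - ref_codes[ends - 1]  # complement code of the terminal base
    end_counts = {b: 0 for b in BASES}
    for code_arr in (left5[clean], right5[clean]):
        vals, cnts = np.unique(code_arr, return_counts=True)
        for v, c in zip(vals, cnts):
            end_counts[BASES[v]] += int(c)

    dup_clean = clean[dup_src] if n_dup else np.zeros(0, dtype=bool)
    n_clean_pairs = int(clean.sum()) + int(dup_clean.sum())
    manifest = Manifest(
        n_pairs=n_total,
        n_unique_fragments=n_unique,
        n_duplicates=n_dup,
        n_contaminant_pairs=int(contaminant.sum()) + int((~dup_clean).sum()),
        n_improper=int(improper.sum()),
        n_nonunique=int(nonunique.sum()),
        n_clean_unique=int(clean.sum()),
        n_clean_pairs=n_clean_pairs,
        total_raw_bases=n_total * 2 * rl,
        mean_depth_clean=float(clean.sum()) * 2 * rl / L,
        clean_fragment_lengths=clean_lengths,
        end_base_counts=end_counts,
        variants=variant_records,
        duplicate_sources=dup_src,
    )
    return SimulatedDataset(pairs=pairs, manifest=manifest, ref=ref, config=cfg)


def simulate_nuclear_depths(
    true_cn: float, mt_mean_depth: float, noise_sd: float, seed: int,
    n_loci: int = 6,
) -> np.ndarray:
    """Per-locus nuclear depths consistent with a given mtDNA copy number.

    Under CN = mt_depth / nuclear_mean * 2, a diploid cell with ``true_cn``
    mitochondrial copies sequenced to ``mt_mean_depth`` shows nuclear loci at
    2 * mt_mean_depth / true_cn; each locus is perturbed by Gaussian noise
    with standard deviation ``noise_sd``.
    """
    if true_cn <= 0 or mt_mean_depth <= 0:
        raise InvalidParameterError("true_cn and mt_mean_depth must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = 2.0 * mt_mean_depth / true_cn
    depths = base + rng.normal(0.0, noise_sd, size=n_loci) if noise_sd > 0 else np.full(n_loci, base)
    return np.clip(depths, 0.0, None)
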