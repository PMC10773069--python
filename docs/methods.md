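# Methods

`mitocap` implements the computational core of a capture-based mitochondrial
DNA (mtDNA) sequencing comparison: quality control of raw reads, removal of
nuclear-embedded mitochondrial sequence (NUMT) contamination, strand-aware
heteroplasmy calling through a fixed filter cascade, depth normalization and
concordance, mtDNA copy-number estimation, and cell-free mtDNA (cf-mtDNA)
fragmentomics. A seeded generator produces synthetic aligned data with the
statistical structure these analyses assume, so every stage is testable
without external downloads or an aligner in the loop.

## The heteroplasmy model and filter cascade

Heteroplasmy — the coexistence of multiple mtDNA alleles in one sample — is
quantified at each site as variant reads / total reads. Candidate
substitutions are accepted only if all five rules hold:

1. **Per-strand support**: ≥ 3 reads carrying the alternative allele on the
   forward strand AND ≥ 3 on the reverse strand. Guards against strand
   artifacts.
2. **Site depth**: total coverage ≥ 100×.
3. **Per-strand VAF**: variant allele fraction ≥ 2% on each strand
   separately (alt on strand / strand depth). This is deliberately a
   *per-strand* fraction, not the overall VAF evaluated twice: only the
   per-strand reading adds information beyond rule 1.
4. **Repeat-region blacklist**: positions 66–71, 303–316, 513–525, 5892,
   3106–3107, 12418–12425 and 16182–16194 (57 sites in rCRS coordinates)
   are excluded; these homopolymer/repeat tracts yield alignment artifacts.
5. **Oxidative-damage guard**: C>A and G>T transversions with overall VAF
   ≤ 10% are excluded as 8-oxoguanine artifacts. The 10% boundary itself is
   rejected (the rule is "VAF ≤ 10%", inclusive).

Multi-allelic sites are evaluated per alternative allele; calls are sorted
by (position, alt) so outputs are canonical. Pileups include only bases with
Phred ≥ 13 (the samtools default), stated explicitly so pileups are
bit-reproducible. Indels are out of scope; calling is substitution-only.

NUMT removal retains exactly the read pairs that are properly paired and
uniquely mapped (MAPQ ≥ 30, not secondary/supplementary) to the
mitochondrial reference. Deduplication removes *exact duplicates*:
pairs whose concatenated mate-1 + mate-2 sequences are byte-identical
(order-sensitive, coordinate-free). Depth matching keeps each pair
independently with probability target/current mean depth — the behaviour of
per-pair Bernoulli downsampling, not exact-count subsampling.

## Coverage and copy number

Relative coverage is per-position depth divided by the total depth of the
whole genome, × 10⁶; profiles therefore sum to one million and are
comparable across runs of different yield. Overlapping mates are both
counted (no overlap correction), deletions and soft-clips contribute
nothing, and coordinates are 1-based closed throughout. Strand-split
profiles (light/heavy, for RNA-derived data) assign a fragment to the
strand its first-in-pair read maps to; the two strand profiles sum
position-wise to the combined profile. Concordance between two profiles is
the standard Pearson product-moment coefficient across positions.

Copy number is the displayed ratio

    CN = mtDNA mean depth / mean depth of six nuclear reference loci × 2,

i.e. mitochondrial copies per diploid cell. The mtDNA mean depth includes
zero-coverage positions in its denominator; the nuclear summary is the
arithmetic mean of six per-locus depths whose identity is configuration
(it never enters the arithmetic — any six labelled loci may be supplied).
The estimate is scale-equivariant: multiplying all depths by a constant
leaves CN unchanged.

## Fragmentomics

Fragment lengths come from alignment template lengths. Each double-stranded
fragment has two 5′ ends — the top strand's at the left coordinate and the
bottom strand's (the complement of the terminal reference base) at the
right — and both are counted by default; a single-end mode exists because
the convention differs between studies, and the choice is surfaced in
output metadata. End bases and motifs are read from the fragment's own
sequence in sequencing orientation by default (so sequencing errors
propagate realistically); a reference-oriented mode supports exact tests.

The size summary reports the normalized histogram, the cumulative curve,
and the fraction of fragments above 158 bp — the conventional cf-mtDNA
long-fragment threshold. End-motif frequencies are normalized by the
expected k-mer composition of the reference, enumerated circularly over all
16,569 starting positions; when both fragment ends are counted, both
strands are enumerated (the reverse complement included), which is the
background under which uniform sampling yields normalized values of 1.

## The synthetic-data generator

The generator emits already-aligned SAM records — positions are known by
construction, so no aligner sits in the test loop — with:

- a circular reference of prescribed length and GC content (the base
  multiset is fixed exactly and shuffled, so GC is within 1/length of
  target); fragments never span the origin, so linear SAM coordinates stay
  unambiguous. A consequence is a triangular coverage ramp over roughly one
  fragment length at each end of the coordinate space.
- 150 bp paired-end reads; fragment lengths drawn from a mixture of
  normals truncated to [read length, reference length], so the mass above
  any threshold has a closed form (`analytic_tail_mass`, via
  `scipy.stats.truncnorm`). Fragments shorter than one read are not
  modelled. The default cf-mtDNA-like mixture is 85% N(166, 20) + 15%
  N(320, 40) — a mononucleosomal peak plus a long tail; a solid-tissue
  model N(400, 50) mirrors 300–500 bp size selection. These defaults are
  illustrative of the sample types, not calibrated to any particular
  cohort.
- 5′-end bias: fragment placement is accepted with probability
  proportional to bias(left 5′ base) × bias(right 5′ base), so the marginal
  end-base law is w·f / Σw·f over the reference background f.
- heteroplasmies planted read-by-read: each read base covering a truth
  position becomes the alternative allele with probability 2·VAF·balance on
  the forward strand and 2·VAF·(1−balance) on the reverse, giving overall
  alt fraction VAF with a controllable strand split. Realized per-strand
  counts are bookkept in the manifest.
- exact duplicates as byte-identical copies of randomly chosen fragments
  (`round(rate × n)` of them). Unique fragments are guaranteed distinct
  (start, length) placements — sampling without replacement — so the
  planted duplicate fraction is exactly what a sequence-identity detector
  recovers. At the densities used this rejection step perturbs the placement
  law negligibly.
- NUMT-like contaminants: a Bernoulli fraction of pairs flagged either
  improperly paired or MAPQ 0, split evenly at random.
- substitution-only, position-uniform sequencing errors (no indels: the
  calling rules are substitution-centric), and a two-level constant quality
  model (Phred 37 default, optional fraction at Phred 25 to exercise the
  Q30 metric).

Everything is driven by one `numpy` Generator, so a fixed seed gives
byte-identical SAM output and manifests.

What the generator deliberately does **not** emulate: capture-probe bias,
GC-dependent coverage waves, PCR-cycle error structure, position-dependent
quality decay, indels, origin-spanning fragments, and alignment ambiguity
(NUMT contamination appears only through flags, not homologous sequence).
Passing tests therefore demonstrate the *computational* correctness of each
stage under the stated statistical model, not robustness to every artifact
of real libraries.

## Numerical and design choices

- "Low-quality read" means mean Phred < 30, classifying whole reads (the
  per-position mean-quality series is also reported); the clean-data
  proportion is measured in bases, not reads, since trimming shortens
  reads.
- End proportions are computed as exact rationals (`fractions.Fraction`),
  so the four proportions sum to exactly 1.
- Pearson r raises on zero-variance profiles rather than returning NaN.
- The heteroplasmy of a call is stored as the exact float quotient
  (alt_fwd + alt_rev) / depth; identities on it are tested through that
  construction.
- The blacklist ships internally as 1-based closed intervals; on disk it is
  BED (0-based half-open), and the conversion is tested.
- Errors are typed (`InvalidParameterError`, `EmptyInputError`,
  `ConsistencyError`, …) and pipeline stages label their errors with the
  stage name.

## Problem sizes in tests and the acceptance script

Recovery checks use simulations sized for precision, not realism: the
filter-cascade oracle runs on 2,000 randomized sites; blacklist enforcement
on 100 seeded full-length (16,569 bp) simulations at ~24,000 pairs each
(coverage high enough that even blacklist sites inside the linear-edge
ramps clear the 100× rule); VAF recovery on 100 seeded 2 kb simulations at
1000×; fragmentomics recovery pools 50–100 seeds of 2,000 fragments. These
sizes give binomial standard errors well inside the asserted 3–4 SD bands.

## Known limitations

- The six nuclear reference loci are configuration, so copy-number output
  is only as good as the supplied nuclear depths; no qPCR calibration.
- The per-strand VAF reading of rule 3 and the two-ends-per-fragment
  end-counting convention are declared choices where conventions differ;
  both have alternates behind flags.
- Coverage near the linear origin is structurally depressed because
  origin-spanning fragments are not simulated; analyses of real circular
  molecules would not show this ramp.
- Statistical significance testing of paired platform differences is out of
  scope; reports emit the raw paired values instead.
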