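# mitocap

Analysis toolkit for **capture-based mitochondrial DNA sequencing**:
strand-aware heteroplasmy calling, mtDNA copy number, coverage concordance,
and cell-free mtDNA (cf-mtDNA) fragmentomics — plus a seeded synthetic-data
generator so the whole pipeline is testable end-to-end without external
data or an aligner.

It is written for people who compare mtDNA sequencing runs — across
platforms, protocols or sample types (tissue, FFPE, PBMC, plasma, urine) —
and need the downstream computations to be exact, reproducible and
independently checkable.

## What it computes

**Heteroplasmy calling.** From properly-paired, uniquely-mapped read pairs
(the NUMT-contamination filter), deduplicated and optionally depth-matched,
a strand-resolved pileup is built and each candidate substitution must pass
five rules: ≥ 3 alt reads per strand; site depth ≥ 100×; per-strand VAF
≥ 2%; position outside the rCRS repeat-region blacklist (66–71, 303–316,
513–525, 5892, 3106–3107, 12418–12425, 16182–16194); and no C>A / G>T
transversion at VAF ≤ 10% (8-oxoguanine guard). The heteroplasmy level of a
call is

```
heteroplasmy = variant reads / total reads at the site
```

**Copy number.**

```
CN = mtDNA mean depth / mean depth of six nuclear reference loci × 2
```

**Coverage.** Per-base depth normalized to parts-per-million of total
mitochondrial depth (values sum to 10⁶), strand-split on request, compared
across runs by Pearson correlation.

**Fragmentomics.** Fragment-size histograms and cumulative curves from
template lengths, the fraction of fragments > 158 bp, 5′-end base
proportions (A/T/G/C ends over all ends), and 5′ end-motif frequencies
normalized by the circular k-mer composition of the reference.

## Worked example

Simulate a sample sequenced on two emulated platforms (same truth set of
five planted heteroplasmies; platform A with a higher duplicate rate,
platform B with a broader fragment-size model), then compare them:

```python
from mitocap import run_pipeline, compare_runs, make_reference, \
    SimulationConfig, TruthVariant, simulate_dataset

ref = make_reference(16569, gc_target=0.44, seed=2024)
truth = [TruthVariant(4512, ref.base(4512), "G", vaf=0.12)]
a = simulate_dataset(ref, truth, SimulationConfig(n_fragments=20000, duplicate_rate=0.18, seed=1))
b = simulate_dataset(ref, truth, SimulationConfig(n_fragments=22000, duplicate_rate=0.08, seed=2))
report = compare_runs(
    run_pipeline(a.pairs, ref, label="A"),
    run_pipeline(b.pairs, ref, label="B"),
)
```

The same experiment, scripted: `python analysis/01_simulate_platforms.py`
through `06_fragmentomics.py`. Output of the depth-matched variant
comparison (`05`):

```
Depth-matched comparison at 285X:
  shared calls:            5 at [1624, 4512, 7800, 11251, 14930]
  platform-derived (A/B):  0 / 0
  planted recovered:       5/5
  substitution spectra: {'C>T': 1, 'G>A': 2, 'T>C': 2} vs {'C>T': 1, 'G>A': 2, 'T>C': 2}
```

Both platforms are first downsampled to the shallower run's mean depth
(285×), then called; every planted heteroplasmy (VAF 4%–90%) is recovered
on both platforms, no platform-derived calls appear in error-free data, and
the substitution spectra agree. The QC driver (`02`) shows why raw yield
and usable depth differ:

```
  platform  q30_read_fraction  duplication_rate  mapping_rate  depth_per_gb
platform_A             0.9803              0.18           1.0       47552.7
platform_B             0.9586              0.08           1.0       53270.3
```

the higher-duplication platform loses more depth per raw gigabase to
deduplication. The fragmentomics driver (`06`) recovers each platform's
size-model tail mass (fraction > 158 bp: 0.817 measured vs 0.821 analytic
for A; 0.856 vs 0.861 for B) and shows matching 5′-end base proportions,
since both runs sample the same molecules.

A command-line interface mirrors the library:
`mitocap simulate | qc | coverage | call | cn | fragments | compare`.

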