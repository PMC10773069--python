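"""Shared setup for the analysis drivers: two emulated sequencing platforms.

Platform A plays the role of a DNBSEQ-style run (higher duplicate rate,
tighter fragment-size range); platform B a NovaSeq-style run (lower
duplication, broader size range, slightly more raw output per mitochondrial
base).  Both sequence the same underlying sample: one reference, one truth
set of heteroplasmies.
"""

from pathlib import Path

from mitocap import SimulationConfig, SizeComponent, TruthVariant, make_reference, simulate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

REF_LENGTH = 16569
GC_TARGET = 0.44
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: (position, vaf) of the sample's heteroplasmies; transitions, clear of the
#: blacklist and of the linear-edge coverage ramps.
TRUTH_SPEC = ((1624, 0.04), (4512, 0.12), (7800, 0.35), (11251, 0.60), (14930, 0.90))

PLATFORM_A = dict(
    label="platform_A",
    n_fragments=20000,
    duplicate_rate=0.18,
    contaminant_rate=0.04,
    base_error_rate=0.0008,
    size_model=(SizeComponent(166.0, 14.0, 0.92), SizeComponent(300.0, 25.0, 0.08)),
    quality_low_fraction=0.02,
)
PLATFORM_B = dict(
    label="platform_B",
    n_fragments=22000,
    duplicate_rate=0.08,
    contaminant_rate=0.04,
    base_error_rate=0.0008,
    size_model=(SizeComponent(166.0, 22.0, 0.80), SizeComponent(330.0, 45.0, 0.20)),
    quality_low_fraction=0.04,
)


def reference(seed=2024):
    return make_reference(REF_LENGTH, GC_TARGET, seed=seed)


def truth_variants(ref):
    return [
        TruthVariant(p, ref.base(p), TRANSITION[ref.base(p)], vaf=v)
        for p, v in TRUTH_SPEC
    ]


def platform_datasets(seed=2024):
    """Simulate both platforms over the same sample; returns (ref, {label: dataset})."""
    ref = reference(seed)
    truth = truth_variants(ref)
    datasets = {}
    for offset, spec in enumerate((PLATFORM_A, PLATFORM_B), start=1):
        spec = dict(spec)
        label = spec.pop("label")
        cfg = SimulationConfig(seed=seed + offset, **spec)
        datasets[label] = simulate_dataset(ref, truth, cfg)
    return ref, datasets
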