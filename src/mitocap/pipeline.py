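"""End-to-end orchestration and two-platform concordance reporting.

``run_pipeline`` composes the analysis stages in the order the comparison
design requires — NUMT retention, deduplication, optional depth matching,
pileup and calling, plus coverage, copy number and fragmentomics — into one
:class:`PlatformRunSummary`.  ``compare_runs`` matches two runs to the
shallower run's mean depth before comparing callsets, then assembles the
comparison surfaces (depth concordance, shared vs platform-derived calls,
copy number, fragment-size and end-base panels) into a
:class:`ComparisonReport`.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .calling import (
    FilterConfig,
    VariantCall,
    build_pileup,
    call_variants,
    compare_callsets,
    downsample_pairs,
    CallsetComparison,
)
from .copy_number import CNEstimate, estimate_cn, mt_mean_depth
from .coverage import (
    DepthProfile,
    RelativeProfile,
    depth_correlation,
    normalize_relative,
    per_base_depth,
)
from .errors import ConsistencyError, EmptyInputError, MitocapError
from .fragmentomics import (
    EndProportions,
    SizeDistribution,
    end_base_proportions,
    extract_fragments,
    size_distribution,
)
from .readqc import QCReport, dedup_pairs, qc_report, retain_mito_pairs
from .reference import ReferenceGenome
from .samio import AlignedPair


@contextmanager
def _stage(name: str):
    """Label errors with the pipeline stage that raised them."""
    try:
        yield
    except MitocapError as exc:
        if not str(exc).startswith(f"{name}:"):
            exc.args = (f"{name}: {exc}",) + exc.args[1:]
        raise


@dataclass
class PlatformRunSummary:
    label: str
    ref: ReferenceGenome
    qc: QCReport
    depth_profile: DepthProfile
    relative_profile: RelativeProfile
    mean_depth: float
    callset: list[VariantCall]
    cn: CNEstimate | None
    size_dist: SizeDistribution
    end_proportions: EndProportions
    motif_table: pd.DataFrame
    final_pairs: list[AlignedPair] = field(repr=False)
    provenance: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    depth_pearson_r: float
    callsets: CallsetComparison
    cn_a: float | None
    cn_b: float | None
    end_proportions_a: dict
    end_proportions_b: dict
    size_dist_a: SizeDistribution
    size_dist_b: SizeDistribution
    fraction_long_a: float
    fraction_long_b: float
    provenance: dict = field(default_factory=dict)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    pairs: list[AlignedPair],
    ref: ReferenceGenome,
    *,
    label: str = "run",
    filter_cfg: FilterConfig = FilterConfig(),
    target_mean_depth: float | None = None,
    nuclear_depths=None,
    motif_k: int = 4,
    seed: int = 0,
) -> PlatformRunSummary:
    """Run every analysis stage on one dataset's aligned pairs.

    Stage order: NUMT retention -> exact-duplicate removal -> optional
    depth matching -> pileup -> filter cascade; relative coverage, copy
    number (when ``nuclear_depths`` is given) and fragmentomics are computed
    from the same post-deduplication pairs.  Deterministic under ``seed``.
    """
    if not pairs:
        raise EmptyInputError("input: no aligned pairs")
    raw_reads = [r for p in pairs for r in p.reads()]

    with _stage("qc"):
        clean_reads = [r for r in raw_reads if r.mean_quality >= 30]
        qc = qc_report(raw_reads, clean_reads, pairs, ref.name)
    with _stage("retain"):
        retained = retain_mito_pairs(pairs, ref.name)
    with _stage("dedup"):
        deduped = dedup_pairs(retained)
    with _stage("downsample"):
        final = (
            downsample_pairs(deduped, target_mean_depth, len(ref), seed)
            if target_mean_depth is not None else deduped
        )
    with _stage("coverage"):
        if not final:
            raise EmptyInputError("no retained pairs to compute coverage from")
        profile = per_base_depth(final, len(ref))
        relative = normalize_relative(profile)
        depth = mt_mean_depth(profile)
    with _stage("call"):
        pileup = build_pileup(final, ref)
        callset = call_variants(pileup, filter_cfg)
    with _stage("copy_number"):
        cn = (
            estimate_cn(depth, nuclear_depths)
            if nuclear_depths is not None else None
        )
    with _stage("fragments"):
        fragments, _ = extract_fragments(final, ref, k=motif_k)
        size_d = size_distribution(fragments)
        ends = end_base_proportions(fragments)
        from .fragmentomics import normalized_end_motifs

        motifs = normalized_end_motifs(fragments, ref, k=motif_k)

    provenance = {
        "tool": f"mitocap {__version__}",
        "seed": seed,
        "stage_order": ["retain", "dedup", "downsample", "pileup", "call"],
        "config_hash": _config_hash(
            {
                "filter": {
                    "min_alt_per_strand": filter_cfg.min_alt_per_strand,
                    "min_site_depth": filter_cfg.min_site_depth,
                    "min_vaf_per_strand": filter_cfg.min_vaf_per_strand,
                    "oxog_vaf_max": filter_cfg.oxog_vaf_max,
                    "blacklist": sorted(filter_cfg.blacklist),
                },
                "target_mean_depth": target_mean_depth,
                "motif_k": motif_k,
            }
        ),
    }
    return PlatformRunSummary(
        label=label, ref=ref, qc=qc,
        depth_profile=profile, relative_profile=relative, mean_depth=depth,
        callset=callset, cn=cn, size_dist=size_d, end_proportions=ends,
        motif_table=motifs, final_pairs=final, provenance=provenance,
    )


def compare_runs(
    a: PlatformRunSummary,
    b: PlatformRunSummary,
    *,
    filter_cfg: FilterConfig = FilterConfig(),
    seed: int = 0,
) -> ComparisonReport:
    """Compare two platform runs after matching their sequencing depths.

    The deeper run is downsampled to the shallower run's mean depth, its
    pileup and callset recomputed, and only then are callsets compared —
    depth matching always precedes the mutation comparison.
    """
    if a.ref.sequence != b.ref.sequence:
        raise ConsistencyError("runs were computed against different references")
    ref = a.ref
    target = min(a.mean_depth, b.mean_depth)

    def matched(run: PlatformRunSummary):
        if run.mean_depth <= target:
            return run.final_pairs, run.callset, run.relative_profile
        pairs = downsample_pairs(run.final_pairs, target, len(ref), seed)
        profile = per_base_depth(pairs, len(ref))
        calls = call_variants(build_pileup(pairs, ref), filter_cfg)
        return pairs, calls, normalize_relative(profile)

    _, calls_a, rel_a = matched(a)
    _, calls_b, rel_b = matched(b)

    report = ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        depth_pearson_r=depth_correlation(rel_a, rel_b),
        callsets=compare_callsets(calls_a, calls_b, len(ref)),
        cn_a=a.cn.cn if a.cn else None,
        cn_b=b.cn.cn if b.cn else None,
        end_proportions_a=a.end_proportions.as_dict(),
        end_proportions_b=b.end_proportions.as_dict(),
        size_dist_a=a.size_dist,
        size_dist_b=b.size_dist,
        fraction_long_a=a.size_dist.fraction_above(),
        fraction_long_b=b.size_dist.fraction_above(),
        provenance={
            "target_mean_depth": target,
            "depth_matching": "before callset comparison",
            "seed": seed,
            "config_hash": _config_hash({"a": a.provenance, "b": b.provenance}),
        },
    )
    return report
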