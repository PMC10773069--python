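"""Independent brute-force oracles used by the test suite.

Everything here is written as a literal, rule-by-rule transcription of the
analysis definitions, deliberately sharing no code with the vectorized
implementations it checks.
"""

from __future__ import annotations

import math

BASES = "ACGT"


def bruteforce_calls(sites, cfg):
    """Literal evaluation of the five filter rules, site by site, alt by alt.

    ``sites`` is an iterable of PileupSite; returns a set of
    (position, alt_base) keys that pass every rule.
    """
    passing = set()
    for site in sites:
        fwd_depth = sum(site.count(b, "+") for b in BASES)
        rev_depth = sum(site.count(b, "-") for b in BASES)
        depth = fwd_depth + rev_depth
        for alt in BASES:
            if alt == site.ref_base or site.ref_base not in BASES:
                continue
            alt_fwd = site.count(alt, "+")
            alt_rev = site.count(alt, "-")
            if alt_fwd + alt_rev == 0:
                continue
            # rule 1: >= 3 alt reads on each strand
            if alt_fwd < cfg.min_alt_per_strand or alt_rev < cfg.min_alt_per_strand:
                continue
            # rule 2: site coverage >= 100X
            if depth < cfg.min_site_depth:
                continue
            # rule 3: VAF >= 2% on both strands
            vaf_fwd = alt_fwd / fwd_depth if fwd_depth else 0.0
            vaf_rev = alt_rev / rev_depth if rev_depth else 0.0
            if vaf_fwd < cfg.min_vaf_per_strand or vaf_rev < cfg.min_vaf_per_strand:
                continue
            # rule 4: not in a repeat-region blacklist position
            if site.position in cfg.blacklist:
                continue
            # rule 5: not an oxo-G-type transversion at VAF <= 10%
            vaf = (alt_fwd + alt_rev) / depth
            oxog_type = (site.ref_base, alt) in (("C", "A"), ("G", "T"))
            if oxog_type and vaf <= cfg.oxog_vaf_max:
                continue
            passing.add((site.position, alt))
    return passing


def bruteforce_duplicate_rate(pairs):
    """Quadratic all-pairs duplicate detection on (seq1, seq2) tuples."""
    seqs = [(p.seq1, p.seq2) for p in pairs]
    n = len(seqs)
    is_dup = [False] * n
    for i in range(n):
        for j in range(i):
            if seqs[i] == seqs[j]:
                is_dup[i] = True
                break
    return sum(is_dup) / n


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson product-moment coefficient."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
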