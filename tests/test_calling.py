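import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocap import (
    FilterConfig,
    build_pileup,
    call_variants,
    compare_callsets,
    downsample_pairs,
    per_base_depth,
    substitution_spectrum,
)
from mitocap.calling import (
    DEFAULT_BLACKLIST_INTERVALS,
    expand_intervals,
    load_blacklist_bed,
)
from mitocap.errors import InvalidParameterError

from conftest import random_sites
from oracles import bruteforce_calls


class TestFilterCascadeExamples:
    """Hand application of the five rules to constructed sites."""

    def test_balanced_five_percent_call(self, make_site):
        site = make_site(position=1000, ref_base="A", alt="G",
                         alt_fwd=5, alt_rev=5, depth=200)
        (call,) = call_variants([site])
        assert call.heteroplasmy == pytest.approx(0.05)
        assert call.vaf_fwd == pytest.approx(0.05)
        assert call.vaf_rev == pytest.approx(0.05)
        assert call.substitution == "A>G"

    def test_strand_support_below_three_rejected(self, make_site):
        site = make_site(alt_fwd=2, alt_rev=7, depth=200)
        assert call_variants([site]) == []

    def test_blacklisted_position_rejected(self, make_site):
        site = make_site(position=303, alt_fwd=20, alt_rev=20, depth=200)
        assert call_variants([site]) == []
        clean = make_site(position=302, alt_fwd=20, alt_rev=20, depth=200)
        assert len(call_variants([clean])) == 1

    def test_oxog_transversion_vaf_boundary(self, make_site):
        low = make_site(ref_base="G", alt="T", alt_fwd=20, alt_rev=20, depth=500)
        assert call_variants([low]) == []  # VAF 0.08 <= 0.10 rejected
        high = make_site(ref_base="G", alt="T", alt_fwd=38, alt_rev=37, depth=500)
        (call,) = call_variants([high])  # VAF 0.15
        assert call.substitution == "G>T"

    def test_oxog_exactly_ten_percent_rejected(self, make_site):
        site = make_site(ref_base="C", alt="A", alt_fwd=25, alt_rev=25, depth=500)
        assert call_variants([site]) == []

    def test_low_coverage_rejected(self, make_site):
        site = make_site(alt_fwd=10, alt_rev=10, depth=90)
        assert call_variants([site]) == []

    def test_per_strand_vaf_rule_is_distinct_from_count_rule(self, make_site):
        # 4 alt reads per strand passes rule 1, but 4/400 = 1% fails rule 3
        site = make_site(alt_fwd=4, alt_rev=4, depth=800)
        assert call_variants([site]) == []

    def test_multiallelic_site_emits_independent_calls(self):
        counts = np.zeros((4, 2), dtype=np.int64)
        counts[0] = (150, 150)  # ref A
        counts[2] = (20, 20)    # alt G
        counts[3] = (15, 15)    # alt T
        from mitocap import PileupSite

        site = PileupSite(position=777, ref_base="A", counts=counts)
        calls = call_variants([site])
        assert [c.alt_base for c in calls] == ["G", "T"]

    def test_audit_reports_failed_rules(self, make_site):
        site = make_site(position=303, alt_fwd=2, alt_rev=7, depth=90)
        audit = []
        call_variants([site], audit=audit)
        (pos, alt, failed) = audit[0]
        assert pos == 303
        assert set(failed) >= {"min_alt_per_strand", "min_site_depth", "blacklist"}


class TestOracleEquivalence:
    def test_matches_bruteforce_on_randomized_sites(self):
        rng = np.random.default_rng(101)
        sites = random_sites(rng, 2000)
        cfg = FilterConfig()
        got = {c.key for c in call_variants(sites, cfg)}
        assert got == bruteforce_calls(sites, cfg)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        sites = random_sites(rng, 100)
        base = {c.key for c in call_variants(sites, FilterConfig())}
        for cfg in (
            FilterConfig(min_alt_per_strand=5),
            FilterConfig(min_site_depth=200),
            FilterConfig(min_vaf_per_strand=0.05),
        ):
            tightened = {c.key for c in call_variants(sites, cfg)}
            assert tightened <= base

    def test_heteroplasmy_identity(self):
        rng = np.random.default_rng(55)
        sites = random_sites(rng, 500)
        for c in call_variants(sites):
            assert c.heteroplasmy == (c.alt_fwd + c.alt_rev) / c.depth
            assert round(c.heteroplasmy * c.depth) == c.alt_fwd + c.alt_rev


class TestBlacklist:
    def test_printed_intervals_expand_to_57_positions(self):
        assert len(expand_intervals(DEFAULT_BLACKLIST_INTERVALS)) == 57

    def test_bundled_bed_matches_builtin_intervals(self):
        import importlib.resources

        with importlib.resources.as_file(
            importlib.resources.files("mitocap.data") / "rcrs_blacklist.bed"
        ) as p:
            assert load_blacklist_bed(p) == expand_intervals(DEFAULT_BLACKLIST_INTERVALS)

    def test_bed_conversion_round_trip(self, tmp_path):
        bed = tmp_path / "bl.bed"
        lines = [
            f"chrM\t{start - 1}\t{end}" for start, end in DEFAULT_BLACKLIST_INTERVALS
        ]
        bed.write_text("\n".join(lines) + "\n")
        assert load_blacklist_bed(bed) == expand_intervals(DEFAULT_BLACKLIST_INTERVALS)


class TestBuildPileup:
    def test_direct_construction(self, make_pair, ref_small):
        pos = 100
        seq = "G" * 30
        pairs = [
            make_pair(read_id=f"r{i}", pos1=pos, seq1=seq, pos2=pos, seq2=seq,
                      strand1="+", strand2="+")
            for i in range(5)
        ]
        pileup = build_pileup(pairs, ref_small)
        site = pileup.site(pos)
        assert site.count("G", "+") == 10  # 5 pairs x 2 forward mates
        assert site.count("G", "-") == 0
        assert pileup.site(2000).depth == 0

    def test_low_quality_bases_excluded(self, make_pair, ref_small):
        p = make_pair(pos1=50, seq1="A" * 30, pos2=50, seq2="A" * 30, phred=10)
        pileup = build_pileup([p], ref_small)
        assert pileup.site(50).depth == 0

    def test_depths_agree_with_per_base_depth(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=600, seed=19)
        pileup = build_pileup(ds.pairs, ref_small)
        profile = per_base_depth(ds.pairs, len(ref_small))
        np.testing.assert_array_equal(pileup.depths, profile.depths)


class TestDownsample:
    def test_identity_when_target_at_or_above_current(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=300, seed=2)
        current = sum(p.aligned_bases for p in ds.pairs) / len(ref_small)
        assert downsample_pairs(ds.pairs, current * 2, len(ref_small), 1) == ds.pairs

    def test_deterministic_under_seed(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=500, seed=2)
        a = downsample_pairs(ds.pairs, 10.0, len(ref_small), seed=7)
        b = downsample_pairs(ds.pairs, 10.0, len(ref_small), seed=7)
        assert a == b

    def test_mean_realized_depth_near_target(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=500, seed=2)
        current = sum(p.aligned_bases for p in ds.pairs) / len(ref_small)
        target = current / 2
        depths = []
        for seed in range(100):
            kept = downsample_pairs(ds.pairs, target, len(ref_small), seed)
            depths.append(sum(p.aligned_bases for p in kept) / len(ref_small))
        # binomial oracle: pair keeps ~ Bin(n, 1/2), depth sd over seeds
        per_pair = current / len(ds.pairs)
        sd_one = np.sqrt(len(ds.pairs) * 0.25) * per_pair
        assert abs(np.mean(depths) - target) <= 3 * sd_one / np.sqrt(100)

    def test_invalid_target_rejected(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=50, seed=2)
        with pytest.raises(InvalidParameterError):
            downsample_pairs(ds.pairs, 0, len(ref_small), 1)


class TestSpectrumAndComparison:
    def test_spectrum_counts(self, make_site):
        calls = call_variants(
            [make_site(position=100, ref_base="A", alt="G", alt_fwd=10, alt_rev=10),
             make_site(position=200, ref_base="T", alt="C", alt_fwd=10, alt_rev=10)]
        )
        spectrum = substitution_spectrum(calls)
        assert spectrum["A>G"] == 1 and spectrum["T>C"] == 1
        assert sum(spectrum.values()) == len(calls) == 2
        assert sum(substitution_spectrum([]).values()) == 0

    def test_identical_callsets_share_everything(self, make_site):
        calls = call_variants([make_site(position=100, alt_fwd=10, alt_rev=10)])
        cmp = compare_callsets(calls, calls, 16569)
        assert cmp.a_only == cmp.b_only == ()
        assert cmp.shared == ((100, "G"),)
        assert cmp.mutation_density_a == pytest.approx(1 / 16.569)

    def test_disjoint_callsets(self, make_site):
        a = call_variants([make_site(position=100, alt_fwd=10, alt_rev=10)])
        b = call_variants([make_site(position=200, alt_fwd=10, alt_rev=10)])
        cmp = compare_callsets(a, b, 16569)
        assert cmp.shared == ()
        assert cmp.a_only == ((100, "G"),) and cmp.b_only == ((200, "G"),)
        assert cmp.spectrum_a_only["A>G"] == 1
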