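import math
from fractions import Fraction

import numpy as np
import pytest

from mitocap import (
    end_base_proportions,
    extract_fragments,
    normalized_end_motifs,
    size_distribution,
)
from mitocap.fragmentomics import FragmentRecord
from mitocap.errors import EmptyInputError
from mitocap.reference import reverse_complement


def frag(length, left="A", right="T", k=1):
    return FragmentRecord(
        start=1, end=length, length=length,
        five_prime_bases=(left, right),
        five_prime_motifs=(left * k, right * k),
    )


class TestExtractFragments:
    def test_coordinate_arithmetic(self, make_pair, ref_small):
        p = make_pair(pos1=101, seq1="A" * 150, pos2=117, seq2="A" * 150,
                      insert_size=166)
        (rec,), skipped = extract_fragments([p], ref_small)
        assert (rec.start, rec.end, rec.length) == (101, 266, 166)
        assert skipped == 0

    def test_reference_orientation_end_bases(self, make_pair, ref_small):
        start, length = 201, 180
        end = start + length - 1
        p = make_pair(
            pos1=start, seq1=ref_small.slice(start, start + 149),
            pos2=end - 149, seq2=ref_small.slice(end - 149, end),
            insert_size=length,
        )
        (rec,), _ = extract_fragments([p], ref_small, k=4, orientation="reference")
        assert rec.five_prime_bases[0] == ref_small.base(start)
        # bottom-strand 5' end is the complement of the last reference base
        assert rec.five_prime_bases[1] == reverse_complement(ref_small.base(end))
        assert rec.five_prime_motifs[0] == ref_small.slice(start, start + 3)
        assert rec.five_prime_motifs[1] == reverse_complement(
            ref_small.slice(end - 3, end)
        )

    def test_sequenced_orientation_matches_reference_when_error_free(
        self, ref_small, simulate
    ):
        ds = simulate(ref_small, n_fragments=300, seed=7)
        seq_recs, _ = extract_fragments(ds.pairs, ref_small, orientation="sequenced")
        ref_recs, _ = extract_fragments(ds.pairs, ref_small, orientation="reference")
        assert [r.five_prime_motifs for r in seq_recs] == [
            r.five_prime_motifs for r in ref_recs
        ]

    def test_pooled_end_counts_match_manifest(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=2000, seed=12)
        recs, _ = extract_fragments(ds.pairs, ref_small)
        from collections import Counter

        counts = Counter(b for r in recs for b in r.five_prime_bases)
        assert dict(counts) == {
            b: n for b, n in ds.manifest.end_base_counts.items() if n
        }

    def test_zero_insert_skipped_with_count(self, make_pair, ref_small):
        good = make_pair(pos1=10, seq1="A" * 30, pos2=10, seq2="A" * 30, insert_size=30)
        bad = make_pair(pos1=10, seq1="A" * 30, pos2=10, seq2="A" * 30, insert_size=0,
                        read_id="bad")
        recs, skipped = extract_fragments([good, bad], ref_small)
        assert len(recs) == 1 and skipped == 1

    def test_first_end_mode_records_single_end(self, make_pair, ref_small):
        p = make_pair(pos1=101, seq1=ref_small.slice(101, 130),
                      pos2=141, seq2=ref_small.slice(141, 170), insert_size=70)
        (rec,), _ = extract_fragments([p], ref_small, ends="first",
                                      orientation="reference")
        assert len(rec.five_prime_bases) == 1


class TestSizeDistribution:
    def test_all_short_fragments(self):
        dist = size_distribution([frag(150) for _ in range(10)])
        assert dist.fraction_above(158) == 0.0

    def test_even_split(self):
        frags = [frag(100)] * 50 + [frag(200)] * 50
        dist = size_distribution(frags)
        assert dist.fraction_above(158) == 0.5
        assert dist.cumulative[-1] == pytest.approx(1.0)

    def test_cumulative_monotone_and_fraction_non_increasing(self):
        rng = np.random.default_rng(4)
        frags = [frag(int(l)) for l in rng.integers(60, 400, 500)]
        dist = size_distribution(frags)
        assert (np.diff(dist.cumulative) >= 0).all()
        assert dist.cumulative[-1] == pytest.approx(1.0)
        fractions = [dist.fraction_above(t) for t in range(50, 450, 25)]
        assert fractions == sorted(fractions, reverse=True)
        assert dist.frequency.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            size_distribution([])


class TestEndProportions:
    def test_single_base(self):
        props = end_base_proportions([frag(100, "A", "A")] * 5)
        assert props.p_A == 1 and props.p_T == props.p_G == props.p_C == 0

    def test_formula_arithmetic(self):
        frags = (
            [frag(100, "A", "A")] * 5     # 10 A ends
            + [frag(100, "T", "T")] * 10  # 20 T ends
            + [frag(100, "G", "G")] * 15  # 30 G ends
            + [frag(100, "C", "C")] * 20  # 40 C ends
        )
        props = end_base_proportions(frags)
        assert (props.p_A, props.p_T, props.p_G, props.p_C) == (
            Fraction(1, 10), Fraction(2, 10), Fraction(3, 10), Fraction(4, 10)
        )

    def test_sum_is_exactly_one(self):
        rng = np.random.default_rng(9)
        bases = "ACGT"
        frags = [
            frag(100, bases[rng.integers(4)], bases[rng.integers(4)])
            for _ in range(333)
        ]
        props = end_base_proportions(frags)
        assert props.p_A + props.p_T + props.p_G + props.p_C == 1

    def test_ambiguous_ends_excluded(self):
        frags = [frag(100, "A", "N"), frag(100, "N", "N")]
        props = end_base_proportions(frags)
        assert props.p_A == 1


class TestNormalizedEndMotifs:
    def test_uniform_sampling_drives_values_to_one(self, ref_small, simulate):
        ds = simulate(ref_small, n_fragments=20000, seed=31)
        recs, _ = extract_fragments(ds.pairs, ref_small, k=1)
        table = normalized_end_motifs(recs, ref_small, k=1)
        n_ends = 2 * len(recs)
        for motif, row in table.iterrows():
            sd = math.sqrt(row["expected"] * (1 - row["expected"]) / n_ends)
            assert abs(row["observed"] - row["expected"]) <= 4 * sd
            assert row["normalized"] == pytest.approx(1.0, abs=5 * sd / row["expected"])

    def test_planted_bias_recovery(self, ref_small, simulate):
        bias = {"A": 2.0, "C": 1.0, "G": 1.0, "T": 1.0}
        ds = simulate(ref_small, n_fragments=20000, end_bias=bias, seed=37)
        recs, _ = extract_fragments(ds.pairs, ref_small, k=1)
        table = normalized_end_motifs(recs, ref_small, k=1)
        # acceptance-weight model: P(end base = b) = w_b f_b / sum w f over the
        # both-strand background f, so normalized_b = w_b / sum w f
        f = table["expected"]
        denom = sum(bias[b] * f[b] for b in "ACGT")
        for b in "ACGT":
            predicted = bias[b] / denom
            assert table.loc[b, "normalized"] == pytest.approx(predicted, rel=0.05)

    def test_expected_frequencies_sum_to_one(self, ref_small):
        recs = [frag(100, "A", "T", k=2)]
        table = normalized_end_motifs(recs, ref_small, k=2)
        assert table["expected"].sum() == pytest.approx(1.0)
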