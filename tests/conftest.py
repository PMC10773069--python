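import numpy as np
import pytest

from mitocap import (
    AlignedPair,
    PileupSite,
    SimulationConfig,
    TruthVariant,
    make_reference,
    rcrs_fixture,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def ref_small():
    """A 3 kb reference at mtDNA-like GC for fast simulations."""
    return make_reference(3000, 0.44, seed=11)


@pytest.fixture(scope="session")
def rcrs():
    return rcrs_fixture()


@pytest.fixture
def make_pair():
    """Factory for hand-built aligned pairs (ungapped, constant quality)."""

    def _make(
        pos1=1,
        seq1="ACGT" * 10,
        pos2=None,
        seq2=None,
        strand1="+",
        strand2="-",
        properly_paired=True,
        unique=True,
        read_id="r0",
        ref_name="chrM",
        phred=37,
        insert_size=None,
    ):
        seq2 = seq2 if seq2 is not None else seq1
        pos2 = pos2 if pos2 is not None else pos1
        if insert_size is None:
            left = min(pos1, pos2)
            right = max(pos1 + len(seq1), pos2 + len(seq2)) - 1
            insert_size = right - left + 1
        return AlignedPair(
            read_id=read_id,
            ref_name=ref_name,
            pos1=pos1,
            pos2=pos2,
            strand1=strand1,
            strand2=strand2,
            properly_paired=properly_paired,
            unique=unique,
            mapq=60 if unique else 0,
            insert_size=insert_size,
            seq1=seq1,
            seq2=seq2,
            qual1=np.full(len(seq1), phred, dtype=np.uint8),
            qual2=np.full(len(seq2), phred, dtype=np.uint8),
        )

    return _make


@pytest.fixture
def make_site():
    """Factory for strand-resolved pileup sites.

    ``alt_fwd``/``alt_rev`` go to ``alt``; the remaining depth is split
    evenly between strands on the reference base.
    """

    def _make(position=1000, ref_base="A", alt="G", alt_fwd=0, alt_rev=0,
              depth=200, fwd_depth=None):
        counts = np.zeros((4, 2), dtype=np.int64)
        bi = "ACGT".index(alt)
        ri = "ACGT".index(ref_base)
        counts[bi, 0] = alt_fwd
        counts[bi, 1] = alt_rev
        rest = depth - alt_fwd - alt_rev
        if fwd_depth is None:
            counts[ri, 0] = rest // 2
            counts[ri, 1] = rest - rest // 2
        else:
            counts[ri, 0] = fwd_depth - alt_fwd
            counts[ri, 1] = rest - (fwd_depth - alt_fwd)
        return PileupSite(position=position, ref_base=ref_base, counts=counts)

    return _make


def random_sites(rng, n, ref_length=16569):
    """Randomized strand-resolved pileup sites spanning the filter boundaries."""
    sites = []
    positions = rng.choice(ref_length, size=n, replace=False) + 1
    for pos in positions:
        ref_base = "ACGT"[rng.integers(4)]
        counts = np.zeros((4, 2), dtype=np.int64)
        depth = int(rng.integers(0, 400))
        ri = "ACGT".index(ref_base)
        # mostly reference, with alt counts hovering around the rule-1/3 cutoffs
        for _ in range(int(rng.integers(0, 3))):
            alt = "ACGT"[rng.integers(4)]
            counts["ACGT".index(alt), 0] += int(rng.integers(0, 8))
            counts["ACGT".index(alt), 1] += int(rng.integers(0, 8))
        rem = max(depth - counts.sum(), 0)
        counts[ri, 0] += rem // 2
        counts[ri, 1] += rem - rem // 2
        sites.append(PileupSite(position=int(pos), ref_base=ref_base, counts=counts))
    return sites


@pytest.fixture
def simulate():
    """Factory: simulate a dataset with keyword overrides on one config."""

    def _simulate(ref, variants=(), **kw):
        kw.setdefault("n_fragments", 2000)
        cfg = SimulationConfig(**kw)
        truth = [
            TruthVariant(
                position=pos,
                ref_base=ref.base(pos),
                alt_base=alt,
                vaf=vaf,
                strand_balance=balance,
            )
            for (pos, alt, vaf, balance) in variants
        ]
        return simulate_dataset(ref, truth, cfg)

    return _simulate


def alt_base_for(ref, pos):
    """A deterministic alternative allele differing from the reference base."""
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[ref.base(pos)]
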