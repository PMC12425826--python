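import numpy as np
import pytest

from pankit.pairwise import (
    align_pair,
    anchor_blocks,
    chain_and_fill,
    chop_blocks,
    ReferenceIndex,
)
from pankit.seqs import GenomeSet

from conftest import random_genome


def _genome(name, seq):
    return GenomeSet(name, [("chr1", seq)])


class TestChopBlocks:
    def test_even_split_with_partial_tail(self):
        g = _genome("a", "A" * 12_000)
        blocks = chop_blocks(g)
        assert [(b.start, b.end) for b in blocks] == [(0, 5000), (5000, 10000), (10000, 12000)]

    def test_short_tail_merged_into_previous(self):
        g = _genome("a", "A" * 5050)
        blocks = chop_blocks(g)
        assert [(b.start, b.end) for b in blocks] == [(0, 5050)]

    def test_short_chromosome_single_block(self):
        g = _genome("a", "A" * 4000)
        blocks = chop_blocks(g)
        assert [(b.start, b.end) for b in blocks] == [(0, 4000)]

    def test_block_size_precondition(self):
        with pytest.raises(ValueError):
            chop_blocks(_genome("a", "A" * 1000), block_size=50)


class TestAnchorBlocks:
    def test_self_identity(self):
        rng = np.random.default_rng(0)
        seq = random_genome(rng, 20_000)
        g = _genome("a", seq)
        hits = anchor_blocks(chop_blocks(g), _genome("r", seq), g)
        assert len(hits) == 4
        for h in hits:
            assert (h.q_start, h.q_end) == (h.r_start, h.r_end)
            assert h.identity == 1.0
            assert h.strand == "+"

    def test_absent_block_has_no_hit(self):
        rng = np.random.default_rng(1)
        ref = _genome("r", random_genome(rng, 10_000))
        query = _genome("q", random_genome(rng, 5_000))
        hits = anchor_blocks(chop_blocks(query), ref, query)
        assert hits == []

    def test_two_copy_repeat_tie_break(self):
        """A block occurring identically at two reference loci anchors at the
        lower reference start, deterministically."""
        rng = np.random.default_rng(2)
        block = random_genome(rng, 5_000)
        filler = random_genome(rng, 35_000)
        ref_seq = filler[:10_000] + block + filler[10_000:30_000] + block + filler[30_000:]
        ref = _genome("r", ref_seq)
        query = _genome("q", block)
        hits = anchor_blocks(chop_blocks(query), ref, query)
        assert len(hits) == 1
        assert hits[0].r_start == 10_000

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            anchor_blocks([], GenomeSet("r", []), _genome("q", "A" * 200))


class TestChainAndFill:
    def test_identity_map_covers_everything(self):
        rng = np.random.default_rng(3)
        seq = random_genome(rng, 30_000)
        q, r = _genome("q", seq), _genome("r", seq)
        cmap = align_pair(q, r)
        arr = cmap.ref_pos["chr1"]
        assert (arr == np.arange(len(seq))).all()

    def test_single_snp_in_gap_matched_with_differing_base(self):
        rng = np.random.default_rng(4)
        seq = random_genome(rng, 30_000)
        pos = 12_345
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        q = _genome("q", seq[:pos] + alt + seq[pos + 1 :])
        r = _genome("r", seq)
        cmap = align_pair(q, r)
        assert cmap.ref_pos["chr1"][pos] == pos  # position matched, base differs

    def test_indel_leaves_inserted_bases_unmatched(self):
        rng = np.random.default_rng(5)
        seq = random_genome(rng, 30_000)
        ins = random_genome(rng, 700)
        q = _genome("q", seq[:15_000] + ins + seq[15_000:])
        r = _genome("r", seq)
        cmap = align_pair(q, r)
        arr = cmap.ref_pos["chr1"]
        assert (arr[15_000 : 15_700] == -1).all()
        assert arr[14_999] == 14_999
        assert arr[15_700] == 15_000

    def test_off_diagonal_repeat_hit_removed(self):
        """A two-copy repeat pulls one block's best hit off-locus; the final
        map stays colinear (the off-diagonal hit is dropped or re-resolved)."""
        rng = np.random.default_rng(6)
        repeat = random_genome(rng, 5_000)
        base = random_genome(rng, 40_000)
        ref_seq = base[:10_000] + repeat + base[10_000:30_000] + repeat + base[30_000:]
        q = _genome("q", ref_seq)
        r = _genome("r", ref_seq)
        cmap = align_pair(q, r)
        arr = cmap.ref_pos["chr1"]
        matched = np.nonzero(arr >= 0)[0]
        assert (np.diff(arr[matched]) > 0).all()  # strictly increasing => colinear
        assert len(matched) / len(arr) > 0.95

    def test_satellite_block_unmatched(self, small_sim):
        genomes, truth = small_sim
        cmap = align_pair(genomes[1], genomes[0])
        sats = [iv for iv in truth.satellite_intervals(1) if iv[0] == "chr1"]
        assert sats
        for chrom, s, e in sats:
            inner = cmap.ref_pos[chrom][s + 50 : e - 50]
            assert (inner < 0).mean() > 0.9

    def test_symmetry_of_matched_positions(self, small_sim):
        """map(q->r) inverted agrees with map(r->q) on >= 99% of positions
        matched in both directions."""
        genomes, _ = small_sim
        fwd = align_pair(genomes[1], genomes[0])
        rev = align_pair(genomes[0], genomes[1])
        f = fwd.ref_pos["chr1"]
        b = rev.ref_pos["chr1"]
        agree = 0
        total = 0
        for qpos in range(0, len(f), 7):
            rpos = f[qpos]
            if rpos < 0 or b[rpos] < 0:
                continue
            total += 1
            agree += int(b[rpos] == qpos)
        assert total > 1000
        assert agree / total >= 0.99

    def test_mismatch_rate_within_min_identity(self, small_sim):
        genomes, _ = small_sim
        q, r = genomes[2], genomes[0]
        cmap = align_pair(q, r)
        qseq, rseq = q.seq("chr1"), r.seq("chr1")
        arr = cmap.ref_pos["chr1"]
        matched = np.nonzero(arr >= 0)[0]
        mism = sum(qseq[i] != rseq[arr[i]] for i in matched[::11])
        assert mism / len(matched[::11]) <= 0.15
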