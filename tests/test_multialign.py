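import numpy as np
import pytest

from pankit.multialign import (
    PangenomeAlignment,
    build_pangenome,
    build_reference_matrices,
    intersect_matrices,
    pick_references,
    resolve_unaligned_blocks,
    sort_and_index,
)
from pankit.seqs import GenomeSet

from conftest import random_genome


def _genomes(*seqs):
    return [GenomeSet(f"acc{i}", [("chr1", s)]) for i, s in enumerate(seqs)]


@pytest.fixture(scope="module")
def base_seq():
    return random_genome(np.random.default_rng(11), 25_000)


class TestDrafts:
    def test_identical_genomes_give_full_identity_drafts(self, base_seq):
        genomes = _genomes(base_seq, base_seq, base_seq)
        drafts = build_reference_matrices(genomes, ["acc0", "acc1"])
        for d in drafts.values():
            mat = d.pos["chr1"]
            expect = np.arange(1, len(base_seq) + 1)
            assert (mat == expect).all()

    def test_private_insertion_absent_from_all_drafts(self, base_seq):
        ins = random_genome(np.random.default_rng(12), 1000)
        with_ins = base_seq[:12_000] + ins + base_seq[12_000:]
        genomes = _genomes(base_seq, with_ins, base_seq)
        drafts = build_reference_matrices(genomes, ["acc0", "acc2"])
        for d in drafts.values():
            row1 = d.pos["chr1"][1]
            present = set(row1[row1 != 0] - 1)
            # inserted positions 12000..12999 of acc1 never appear as targets
            assert not (present & set(range(12_000, 13_000)))

    def test_single_reference_errors(self, base_seq):
        genomes = _genomes(base_seq, base_seq)
        with pytest.raises(ValueError):
            build_reference_matrices(genomes, ["acc0"])
        with pytest.raises(ValueError):
            build_reference_matrices(genomes, ["acc0", "nope"])


class TestIntersection:
    def test_identical_drafts_survive_fully(self, base_seq):
        genomes = _genomes(base_seq, base_seq, base_seq)
        drafts = build_reference_matrices(genomes, ["acc0", "acc1"])
        skel = intersect_matrices(drafts)
        assert skel.pos["chr1"].shape[1] == len(base_seq)

    def test_draft_order_invariance(self, small_sim):
        genomes, _ = small_sim
        drafts = build_reference_matrices(genomes, ["acc0", "acc1", "acc2"])
        skel_a = intersect_matrices(drafts)
        reordered = {k: drafts[k] for k in ["acc2", "acc0", "acc1"]}
        skel_b = intersect_matrices(reordered)
        # same set of surviving column tuples regardless of draft order
        def tuples(skel):
            out = set()
            for rname, pos in skel.pos.items():
                out |= {tuple(col) for col in pos.T}
            return out
        assert tuples(skel_a) == tuples(skel_b)

    def test_mismatched_accession_sets_error(self, base_seq):
        g3 = _genomes(base_seq, base_seq, base_seq)
        d3 = build_reference_matrices(g3, ["acc0", "acc1"])
        g2 = _genomes(base_seq, base_seq)
        d2 = build_reference_matrices(g2, ["acc0", "acc1"])
        mixed = {"a": d3["acc0"], "b": d2["acc1"]}
        with pytest.raises(ValueError):
            intersect_matrices(mixed)


class TestResolveAndSort:
    def test_private_insertion_spliced_as_gap_columns(self, base_seq):
        ins = random_genome(np.random.default_rng(13), 1000)
        with_ins = base_seq[:12_000] + ins + base_seq[12_000:]
        genomes = _genomes(base_seq, with_ins, base_seq)
        aln = build_pangenome(genomes, references=["acc0", "acc2"])
        # pangenome length = shared length + private insertion
        assert aln.total_columns == len(base_seq) + 1000
        aln.assert_monotonic()

    def test_identical_genomes_pangenome_length_equals_genome_length(self, base_seq):
        genomes = _genomes(base_seq, base_seq, base_seq)
        aln = build_pangenome(genomes, references=["acc0", "acc1"])
        assert aln.total_columns == len(base_seq)

    def test_oversized_block_kept_as_private_columns(self, base_seq):
        big = random_genome(np.random.default_rng(14), 35_000)
        with_big = base_seq[:12_000] + big + base_seq[12_000:]
        genomes = _genomes(base_seq, with_big, base_seq)
        aln = build_pangenome(genomes, references=["acc0", "acc2"], max_block=30_000)
        assert aln.total_columns == len(base_seq) + 35_000
        # the oversized block occupies accession-private columns
        chrom = aln.chromosomes[0]
        row1 = chrom.pos[1]
        private = ((chrom.pos != 0).sum(axis=0) == 1) & (row1 != 0)
        assert private.sum() >= 35_000

    def test_index_round_trip(self, small_alignment):
        _, _, aln = small_alignment
        rng = np.random.default_rng(15)
        chrom = aln.chromosomes[0]
        for _ in range(100):
            col = int(rng.integers(chrom.n_columns))
            for ai, acc in enumerate(aln.accessions):
                pos = aln.from_pangenome(0, col, acc)
                if pos is not None:
                    assert aln.to_pangenome(acc, chrom.acc_chrom[ai], pos) == (0, col)

    def test_sort_requires_anchor_and_sorts_monotonically(self, small_alignment):
        _, _, aln = small_alignment
        with pytest.raises(ValueError):
            sort_and_index(aln, [])
        out = sort_and_index(aln, list(aln.accessions))
        first = out.chromosomes[0].pos[0]
        vals = first[first != 0]
        assert (np.diff(vals) > 0).all()

    def test_monotonicity_invariant_holds(self, small_alignment):
        _, _, aln = small_alignment
        aln.assert_monotonic()

    def test_pan_length_lower_bound(self, small_alignment):
        genomes, _, aln = small_alignment
        assert aln.total_columns >= max(sum(g.lengths) for g in genomes)


def test_pick_references_spread_and_count(small_sim):
    genomes, _ = small_sim
    refs = pick_references(genomes)
    assert len(refs) == min(4, len(genomes))
    assert len(set(refs)) == len(refs)


def test_from_gapped_and_monotonic_assertion():
    aln = PangenomeAlignment.from_gapped({"a": "AC-GT", "b": "ACTGT"})
    chrom = aln.chromosomes[0]
    assert chrom.n_columns == 5
    assert aln.from_pangenome(0, 2, "a") is None
    assert aln.from_pangenome(0, 2, "b") == 2
    aln.assert_monotonic()
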