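import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pankit.multialign import PangenomeAlignment
from pankit.variants import (
    DEFAULT_LENGTH_CLASS_EDGES,
    SVLocus,
    call_snps,
    classify_all,
    classify_sv,
    consensus_allele,
    extract_sv_loci,
    infer_polarity,
    length_class,
)


def aln_of(*rows):
    return PangenomeAlignment.from_gapped({f"a{i}": r for i, r in enumerate(rows)})


class TestCallSnps:
    def test_monomorphic_alignment_has_no_snps(self):
        aln = aln_of("ACGTACGT", "ACGTACGT", "ACGTACGT")
        assert call_snps(aln, "all") == []
        assert call_snps(aln, "isolated") == []

    def test_single_substitution_called_in_both_modes(self):
        aln = aln_of("ACGTACGT", "ACGAACGT", "ACGTACGT")
        for mode in ("all", "isolated"):
            snps = call_snps(aln, mode)
            assert len(snps) == 1
            assert snps[0].column == 3
            assert snps[0].bases == "TAT"

    def test_adjacent_differences_fail_isolated_mode(self):
        aln = aln_of("AAACCGGG", "AAATTGGG")
        assert len(call_snps(aln, "all")) == 2
        assert call_snps(aln, "isolated") == []

    def test_gap_and_n_columns_disqualified(self):
        aln = aln_of("AC-T", "ACGT", "AAGT")  # column 1 polymorphic+gap-free? no: A/C
        # column 1: C,C,A -> polymorphic, gap-free -> SNP; column 2 has gap
        assert [s.column for s in call_snps(aln, "all")] == [1]
        aln2 = aln_of("ANT", "AGT")
        assert call_snps(aln2, "all") == []

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            call_snps(aln_of("AC", "AC"), "weird")

    def test_vcf_projection_uses_first_accession(self):
        aln = aln_of("ACGT", "ACAT")
        (snp,) = call_snps(aln, "all")
        assert snp.ref_pos == 2 and snp.ref_base == "G" and snp.alt_bases == ("A",)
        assert snp.genotypes == (0, 1)


class TestExtractLoci:
    def test_single_absence_run(self):
        aln = aln_of("AAAA" + "C" * 6 + "TTTT", "AAAA" + "-" * 6 + "TTTT", "AAAA" + "C" * 6 + "TTTT")
        (loc,) = extract_sv_loci(aln)
        assert (loc.start, loc.end) == (4, 10)
        assert loc.allele_lengths == [6, 0, 6]
        assert not loc.terminal

    def test_two_runs_split_by_aligned_column(self):
        aln = aln_of("AA--C--TT", "AACCCCCTT")
        loci = extract_sv_loci(aln)
        assert len(loci) == 2
        assert [(l.start, l.end) for l in loci] == [(2, 4), (5, 7)]

    def test_terminal_run_flagged(self):
        aln = aln_of("---ACGT", "CCCACGT")
        (loc,) = extract_sv_loci(aln)
        assert loc.terminal
        assert classify_all(aln) == []  # terminal excluded by default


def brute_force_class(lengths, s):
    """Independent oracle: test every allele against both thresholds."""
    L = max(lengths)
    for x in lengths:
        if not (x < (1 - s) * L or x > s * L):
            return "cSV"
    return "sSV"


class TestClassify:
    def test_worked_example(self):
        loc = SVLocus("sv", "c", 0, 10, ["A" * 1000, "A" * 998, "", "A" * 50])
        classify_sv(loc, s=0.9)
        assert loc.sv_class == "sSV"
        assert loc.presence_set == frozenset({0, 1})
        assert loc.absence_set == frozenset({2, 3})
        assert loc.presence_frequency == 0.5

    def test_intermediate_allele_is_complex(self):
        loc = SVLocus("sv", "c", 0, 10, ["A" * 1000, "A" * 500, ""])
        assert classify_sv(loc, s=0.9).sv_class == "cSV"
        assert classify_sv(loc, s=0.8).sv_class == "cSV"

    def test_invalid_s_errors(self):
        loc = SVLocus("sv", "c", 0, 10, ["A" * 10, ""])
        for bad in (0.5, 0.2, 1.5):
            with pytest.raises(ValueError):
                classify_sv(loc, s=bad)

    def test_exhaustive_grid_matches_oracle(self):
        fracs = (0.0, 0.05, 0.5, 0.95, 1.0)
        for L in (10, 100, 1000):
            lengths_pool = sorted({int(round(f * L)) for f in fracs})
            for n in (2, 4, 8):
                for combo in itertools.combinations_with_replacement(lengths_pool, n):
                    if max(combo) == 0:
                        continue
                    for s in (0.8, 0.9, 0.95):
                        loc = SVLocus("sv", "c", 0, 1, ["A" * x for x in combo])
                        assert classify_sv(loc, s=s).sv_class == brute_force_class(combo, s)

    def test_threshold_monotonicity_on_grid(self):
        """sSV at a stricter s stays sSV at a looser s."""
        fracs = (0.0, 0.05, 0.5, 0.95, 1.0)
        for n in (2, 4):
            for combo in itertools.combinations_with_replacement(
                [int(round(f * 1000)) for f in fracs], n
            ):
                if max(combo) == 0:
                    continue
                states = []
                for s in (0.95, 0.9, 0.8):
                    loc = SVLocus("sv", "c", 0, 1, ["A" * x for x in combo])
                    states.append(classify_sv(loc, s=s).sv_class)
                for strict, loose in zip(states, states[1:]):
                    assert not (strict == "sSV" and loose == "cSV")


class TestPolarity:
    def _locus(self, presence, n):
        alleles = ["A" * 500 if i in presence else "" for i in range(n)]
        return classify_sv(SVLocus("sv", "c", 0, 1, alleles), s=0.9)

    def test_rare_presence_is_likely_insertion(self):
        loc = self._locus({0, 1}, 27)
        assert infer_polarity(loc) == "likely_insertion"

    def test_rare_absence_is_likely_deletion(self):
        loc = self._locus(set(range(27)) - {5}, 27)
        assert infer_polarity(loc) == "likely_deletion"

    def test_intermediate_frequency_unpolarized(self):
        loc = self._locus(set(range(13)), 27)
        assert infer_polarity(loc) == "unpolarized"

    def test_non_ssv_rejected(self):
        loc = classify_sv(SVLocus("sv", "c", 0, 1, ["A" * 1000, "A" * 500, ""]), s=0.9)
        with pytest.raises(ValueError):
            infer_polarity(loc)


class TestConsensus:
    def test_single_and_identical_alleles(self):
        loc = classify_sv(SVLocus("sv", "c", 0, 1, ["ACGTACGTAC", ""]), s=0.9)
        assert consensus_allele(loc) == "ACGTACGTAC"
        loc2 = classify_sv(SVLocus("sv", "c", 0, 1, ["ACGTACGTAC", "ACGTACGTAC", ""]), s=0.9)
        assert consensus_allele(loc2) == "ACGTACGTAC"

    def test_medoid_prefers_majority_sequence(self):
        base = "ACGT" * 30
        divergent = base[:40] + "TTTTT" + base[45:]
        loc = classify_sv(SVLocus("sv", "c", 0, 1, [base, base, divergent, ""]), s=0.9)
        assert consensus_allele(loc) == base

    def test_no_presence_allele_errors(self):
        loc = classify_sv(SVLocus("sv", "c", 0, 1, ["", "A" * 400]), s=0.9)
        loc.presence_set = frozenset()
        with pytest.raises(ValueError):
            consensus_allele(loc)


@settings(max_examples=50, deadline=None)
@given(hst.integers(min_value=1, max_value=50_000))
def test_length_class_partitions_every_length(L):
    cls = length_class(L)
    all_classes = [length_class(x) for x in (1, 15, 100, 500, 1000, 5000, 20000)]
    edges = DEFAULT_LENGTH_CLASS_EDGES
    matches = [
        lo <= L < hi for lo, hi in zip(edges, edges[1:])
    ] + [L >= edges[-1]]
    assert sum(matches) == 1  # exactly one bin
    assert cls in all_classes + [f">={edges[-1]}"]


def test_isolated_count_never_exceeds_all_count(small_alignment):
    _, _, aln = small_alignment
    assert len(call_snps(aln, "isolated")) <= len(call_snps(aln, "all"))
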