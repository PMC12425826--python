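import numpy as np
import pytest

from pankit.localalign import global_identity
from pankit.synthetic import (
    SimulationConfig,
    make_te_library,
    simulate_call_set,
    simulate_pangenome,
)


def test_te_library_deterministic_and_bounds():
    lib1 = make_te_library(6, (400, 6000), seed=1)
    lib2 = make_te_library(6, (400, 6000), seed=1)
    assert [f.consensus for f in lib1] == [f.consensus for f in lib2]
    assert all(400 <= len(f.consensus) <= 6000 for f in lib1)
    single = make_te_library(1, (400, 6000), seed=3)
    assert len(single) == 1
    with pytest.raises(ValueError):
        make_te_library(2, (100, 200), seed=0)


def test_te_library_pairwise_identity_oracle():
    """Every family pair stays below 0.6 global-alignment identity,
    verified with the edit-distance alignment as independent check."""
    lib = make_te_library(6, (400, 6000), seed=1)
    fams = [f.consensus for f in lib]
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            assert global_identity(fams[i], fams[j]) < 0.6


def test_zero_rates_give_identical_genomes():
    cfg = SimulationConfig(
        n_accessions=5, n_chromosomes=1, chrom_length=5000, snp_rate=0.0,
        n_insertions=0, n_deletions=0, n_satellites=0,
    )
    genomes, truth = simulate_pangenome(cfg, seed=4)
    anc = truth.ancestor.seq("chr1")
    assert all(g.seq("chr1") == anc for g in genomes)
    assert not truth.snps and not truth.insertions and not truth.deletions


def test_insertions_present_verbatim_in_carriers(small_sim):
    genomes, truth = small_sim
    for ins in truth.insertions:
        for acc in range(truth.n_accessions):
            hit = ins.sequence in genomes[acc].seq(ins.chrom)
            if acc in ins.carriers:
                assert hit
    # carriers are proper non-empty subsets
    for ev in truth.insertions + truth.deletions:
        assert 0 < len(ev.carriers) < truth.n_accessions


def test_snp_count_matches_binomial_expectation():
    cfg = SimulationConfig(
        n_accessions=4, n_chromosomes=1, chrom_length=100_000, snp_rate=0.002,
        n_insertions=0, n_deletions=0, n_satellites=0,
    )
    _, truth = simulate_pangenome(cfg, seed=5)
    expected = 4 * 100_000 * 0.002
    sd = np.sqrt(4 * 100_000 * 0.002 * (1 - 0.002))
    assert abs(len(truth.snps) - expected) < 3 * sd


def test_truth_ledger_reproduces_genomes(small_sim):
    genomes, truth = small_sim
    for acc, g in enumerate(genomes):
        rebuilt = truth.apply(acc)
        assert rebuilt.chromosomes == g.chromosomes


def test_determinism_byte_identical():
    cfg = SimulationConfig(n_accessions=3, n_chromosomes=1, chrom_length=20_000,
                           n_insertions=3, n_deletions=2, n_satellites=1,
                           te_families=2, te_length_range=(400, 1000),
                           satellite_copies=(10, 15))
    g1, t1 = simulate_pangenome(cfg, seed=9)
    g2, t2 = simulate_pangenome(cfg, seed=9)
    assert [g.chromosomes for g in g1] == [g.chromosomes for g in g2]
    assert t1.snps == t2.snps and t1.insertions == t2.insertions


def test_satellites_are_tandem_and_flagged(small_sim):
    _, truth = small_sim
    assert truth.satellites
    for sat in truth.satellites:
        assert len(sat.unit) <= 180
        anc = truth.ancestor.seq(sat.chrom)[sat.start : sat.end]
        assert anc == (sat.unit * (len(anc) // len(sat.unit) + 1))[: len(anc)]


def test_projection_tracks_events(small_sim):
    genomes, truth = small_sim
    anc = truth.ancestor
    rng = np.random.default_rng(0)
    for acc in range(truth.n_accessions):
        for _ in range(50):
            chrom, seq = anc.chromosomes[0]
            pos = int(rng.integers(len(seq)))
            proj = truth.project(acc, chrom, pos)
            if proj is not None:
                assert genomes[acc].seq(chrom)[proj] in "ACGT"
                # non-carrier base equals ancestor unless a SNP hit this site
                snp_here = any(
                    s.pos == pos and s.chrom == chrom and acc in s.carriers
                    for s in truth.snps
                )
                if not snp_here:
                    assert genomes[acc].seq(chrom)[proj] == seq[pos]


class TestSimulateCallSet:
    def test_zero_rates_reproduce_truth(self):
        truth = list(range(0, 500, 5))
        cs = simulate_call_set(truth, 0.0, 0.0, 0.0, 0, seed=1)
        assert cs.calls == set(truth)
        assert cs.coverage_mask >= set(truth)
        assert not cs.het_calls

    def test_full_fnr_empties_calls(self):
        cs = simulate_call_set(list(range(100)), 0.0, 1.0, 0.0, 0, seed=1)
        assert cs.calls == set()

    def test_dropped_count_is_reproducible_binomial(self):
        truth = list(range(1000))
        cs1 = simulate_call_set(truth, 0.0, 0.1, 0.0, 0, seed=7)
        cs2 = simulate_call_set(truth, 0.0, 0.1, 0.0, 0, seed=7)
        assert cs1.dropped == cs2.dropped
        # 3-sigma band around Binomial(1000, 0.1)
        assert abs(len(cs1.dropped) - 100) < 3 * np.sqrt(1000 * 0.1 * 0.9)

    def test_unachievable_fdr_errors(self):
        with pytest.raises(ValueError):
            simulate_call_set([1, 2, 3], 1.0, 0.0, 0.0, 0, seed=1)

    def test_het_calls_injected(self):
        cs = simulate_call_set(list(range(100)), 0.0, 0.0, 0.0, 5, seed=2)
        assert len(cs.het_calls) == 5
        assert cs.het_calls <= cs.calls
        assert not (cs.het_calls & set(range(100)))
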