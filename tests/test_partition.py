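import numpy as np
import pytest

from mitotwin.io import MitoGenome, Read, ReadSet, reverse_complement
from mitotwin.partition import (
    align_identity,
    assign_reads,
    consensus_from_assignment,
    coverage_summary,
    decontaminate,
    kmer_repeat_scan,
    mixture_fraction,
    screen_contigs,
    wilson_interval,
)
from mitotwin.simulate import (
    SimConfig,
    mix_reads,
    simulate_long_reads,
    simulate_short_reads,
)


class TestAlignIdentity:
    def test_exact_substring_identity_one(self, truth):
        frag = truth.genome_m1.sequence[2000:3000]
        hit = align_identity(frag, truth.genome_m1)
        assert hit.identity == 1.0
        assert hit.span[0] == 2000

    def test_reverse_complement_found(self, truth):
        frag = reverse_complement(truth.genome_m1.sequence[2000:3000])
        hit = align_identity(frag, truth.genome_m1)
        assert hit.identity == 1.0
        assert hit.strand == "-"

    def test_origin_spanning_read(self, truth):
        seq = truth.genome_m1.sequence
        frag = seq[-500:] + seq[:500]
        hit = align_identity(frag, truth.genome_m1)
        assert hit.identity == 1.0
        assert hit.span[0] == len(seq) - 500

    def test_cross_molecule_identity_near_divergence(self, truth):
        """An M1 fragment against the M2 reference loses roughly the
        inter-molecule divergence."""
        frag = truth.genome_m1.sequence[5000:7000]
        hit = align_identity(frag, truth.genome_m2)
        assert 0.85 <= hit.identity <= 0.95

    def test_unrelated_sequence_reports_zero(self, truth, rng):
        junk = "".join(rng.choice(list("ACGT"), size=800))
        hit = align_identity(junk, truth.genome_m1)
        assert hit.identity == 0.0 and hit.span == (0, 0)


class TestAssignReads:
    def test_high_accuracy_on_synthetic_mixture(self, truth, config):
        r1 = simulate_long_reads(truth.genome_m1, config, n_reads=120,
                                 prefix="m1_")
        r2 = simulate_long_reads(truth.genome_m2, config, n_reads=40,
                                 prefix="m2_")
        mix = mix_reads(r1, r2, 0.145, seed=1)
        table = assign_reads(mix, truth.genome_m1, truth.genome_m2)
        called = [r for r in table if r.call in ("M1", "M2")]
        assert called, "no reads called"
        accuracy = sum(r.call == r.true_origin for r in called) / len(called)
        assert accuracy >= 0.99
        # partition property: every read exactly one call
        assert sum(table.counts().values()) == len(mix)

    def test_tie_is_unassigned(self, truth):
        # a read from the region where M1 == M2 is equally identical to both
        read = Read("tie", truth.genome_m1.sequence[:600])
        seq = truth.genome_m1.sequence[:600]
        g1 = MitoGenome("a", seq + "A" * 50, circular=False)
        g2 = MitoGenome("b", seq + "C" * 50, circular=False)
        table = assign_reads([read], g1, g2, min_len=100)
        assert table.records[0].call == "unassigned"

    def test_short_read_filtered(self, truth):
        read = Read("short", truth.genome_m1.sequence[:400])
        table = assign_reads([read], truth.genome_m1, truth.genome_m2)
        assert table.records[0].call == "too_short"

    def test_label_swap_symmetry(self, truth, config):
        reads = list(simulate_long_reads(truth.genome_m1, config, n_reads=20,
                                         prefix="x_"))
        t_ab = assign_reads(reads, truth.genome_m1, truth.genome_m2)
        t_ba = assign_reads(reads, truth.genome_m2, truth.genome_m1)
        swap = {"M1": "M2", "M2": "M1", "unassigned": "unassigned",
                "too_short": "too_short"}
        assert [swap[r.call] for r in t_ab] == [r.call for r in t_ba]


class TestScreenContigs:
    def test_exact_fragment_goes_primary(self, truth):
        contigs = [("c1", truth.genome_m1.sequence[100:1200])]
        out = screen_contigs(contigs, truth.genome_m1, truth.genome_m2)
        assert out["primary"] == ["c1"]

    def test_m2_contigs_go_secondary(self, truth):
        contigs = [(f"s{i}", truth.genome_m2.sequence[i * 2000:(i + 1) * 2000])
                   for i in range(3)]
        out = screen_contigs(contigs, truth.genome_m1, truth.genome_m2)
        assert out["secondary"] == [c[0] for c in contigs]

    def test_chimera_is_ambiguous(self, truth):
        # a half-half chimera diverges ~5% from both molecules; screened at
        # a 4% threshold it clears neither side and must stay ambiguous
        chimera = (truth.genome_m1.sequence[0:1000]
                   + truth.genome_m2.sequence[1000:2000])
        out = screen_contigs([("x", chimera)], truth.genome_m1,
                             truth.genome_m2, min_div=0.04)
        assert out["ambiguous"] == ["x"]


class TestCoverage:
    def test_single_full_molecule_read(self, truth):
        read = Read("full", truth.genome_m1.sequence, platform="long",
                    true_origin="M1")
        table = assign_reads([read], truth.genome_m1, truth.genome_m2)
        cov = coverage_summary(table, truth.genome_m1, "M1")
        assert cov.breadth_pct == 100.0
        assert cov.depth_min == cov.depth_max == 1

    def test_no_reads_gives_null_stats(self, truth):
        table = assign_reads([], truth.genome_m1, truth.genome_m2)
        cov = coverage_summary(table, truth.genome_m1, "M1")
        assert cov.breadth_pct == 0.0 and cov.depth_mean is None

    def test_major_molecule_full_breadth(self, truth, config):
        reads = simulate_long_reads(truth.genome_m1, config, n_reads=120,
                                    prefix="c_")
        table = assign_reads(reads, truth.genome_m1, truth.genome_m2)
        cov = coverage_summary(table, truth.genome_m1, "M1")
        assert cov.breadth_pct >= 99.9


class TestMixtureFraction:
    def test_printed_counts_reproduce_study_share(self):
        est = mixture_fraction(176_980, 30_005)
        assert round(100 * est.minor_fraction, 1) == 14.5
        assert est.n_assignable == 206_985

    def test_zero_minor(self):
        est = mixture_fraction(100, 0)
        assert est.minor_fraction == 0.0

    def test_wilson_interval_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(8, 40), (30005, 206985), (0, 10), (10, 10)]:
            lo, hi = wilson_interval(k, n)
            ref_lo, ref_hi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-9)
            assert hi == pytest.approx(ref_hi, abs=1e-9)


class TestConsensus:
    def test_error_free_reads_reconstruct_genome(self, truth):
        cfg = SimConfig(seed=6, long_error_sub=0.0, long_error_ins=0.0,
                        long_error_del=0.0, full_molecule_prob=0.05)
        reads = simulate_long_reads(truth.genome_m1, cfg, n_reads=120,
                                    prefix="cf_")
        table = assign_reads(reads, truth.genome_m1, truth.genome_m2)
        consensus, flagged = consensus_from_assignment(
            table, reads, truth.genome_m1, "M1")
        assert consensus.sequence == truth.genome_m1.sequence
        assert not flagged

    def test_noisy_short_reads_recover_genome(self, truth):
        cfg = SimConfig(seed=7)
        reads = simulate_short_reads(truth.genome_m1, cfg, depth=50,
                                     prefix="ns_")
        table = assign_reads(reads, truth.genome_m1, truth.genome_m2,
                             min_len=50)
        # short reads over ultra-conserved stretches cannot be assigned,
        # leaving ~1% breadth holes, so the consensus gate is relaxed here
        consensus, _ = consensus_from_assignment(
            table, reads, truth.genome_m1, "M1", min_breadth=95.0)
        mismatches = sum(a != b for a, b in
                         zip(consensus.sequence, truth.genome_m1.sequence))
        assert mismatches / len(consensus.sequence) <= 1e-4

    def test_low_breadth_raises(self, truth, config):
        reads = simulate_long_reads(truth.genome_m1, config, n_reads=2,
                                    prefix="lb_")
        table = assign_reads(reads, truth.genome_m1, truth.genome_m2)
        with pytest.raises(Exception, match="breadth|coverage"):
            consensus_from_assignment(table, reads, truth.genome_m1, "M1")


class TestKmerRepeatScan:
    def test_tandem_duplication_flagged(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=4000))
        block = base[1000:1300]
        genome_seq = base[:1300] + block + base[1300:]  # exact tandem copy
        genome = MitoGenome("dup", genome_seq, circular=False)
        reads = [genome_seq[i:i + 300] for i in range(0, len(genome_seq) - 300, 50)]
        res = kmer_repeat_scan(reads, genome, k=71)
        assert res.regions, "duplicated block not flagged"
        flagged_span = (res.regions[0][0], res.regions[-1][1])
        assert flagged_span[0] >= 900 and flagged_span[1] <= 1800

    def test_unique_genome_unflagged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        genome = MitoGenome("u", seq, circular=False)
        reads = [seq[i:i + 300] for i in range(0, 3700, 50)]
        res = kmer_repeat_scan(reads, genome, k=71)
        assert res.regions == []

    def test_triplicated_nc_blocks_flagged(self, truth, config):
        reads = [r.sequence for r in
                 simulate_short_reads(truth.genome_m1, config, depth=20,
                                      prefix="k_")]
        res = kmer_repeat_scan(reads, truth.genome_m1, k=71)
        nc = [a for a in truth.genome_m1.annotations if a.kind == "NC"]
        covered = sum(
            1 for a in nc
            if any(r[0] < a.end and a.start < r[1] for r in res.regions)
        )
        assert covered == len(nc)

    def test_reads_shorter_than_k_counted(self, truth):
        res = kmer_repeat_scan(["ACGT"], truth.genome_m1, k=71,
                               expected_depth=1)
        assert res.n_too_short == 1


class TestDecontaminate:
    def test_contaminant_purged_targets_kept(self, truth, rng):
        cfg = SimConfig(seed=8)
        target = simulate_long_reads(truth.genome_m1, cfg, n_reads=30,
                                     prefix="t_")
        rat = MitoGenome("rat", "".join(rng.choice(list("ACGT"), size=16000)),
                         circular=True)
        contam = simulate_long_reads(
            MitoGenome("rat", rat.sequence, circular=True,
                       molecule_tag="other"),
            cfg, n_reads=5, prefix="r_")
        pool = ReadSet(list(target) + list(contam))
        kept, purged = decontaminate(pool, rat)
        assert {r.id for r in purged} == {r.id for r in contam}
        assert len(kept) + len(purged) == len(pool)

    def test_no_hits_keeps_everything(self, truth, config, rng):
        reads = simulate_long_reads(truth.genome_m1, config, n_reads=10,
                                    prefix="n_")
        rat = MitoGenome("rat", "".join(rng.choice(list("ACGT"), size=16000)))
        kept, purged = decontaminate(reads, rat)
        assert len(purged) == 0 and len(kept) == len(reads)
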