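import numpy as np
import pytest

from mitotwin.io import GeneAnnotation, MitoGenome, reverse_complement
from mitotwin.qc import (
    base_composition,
    find_hairpins,
    fold_trna,
    mito_translate,
    scan_ol_stemloop,
    site_class_fraction,
    translate_cds,
)
from mitotwin.simulate import make_trna_sequence, ANTICODONS


class TestComposition:
    def test_homopolymer(self):
        rep = base_composition("AAAA")
        assert rep.percentages["G"] == 0.0
        assert rep.percentages["A"] == 100.0

    def test_uniform_random_near_quarter(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        rep = base_composition(seq)
        assert abs(rep.percentages["G"] - 25.0) <= 1.0

    def test_n_excluded_from_denominator(self):
        rep = base_composition("GGNN")
        assert rep.percentages["G"] == 100.0

    def test_percentages_sum_to_hundred(self, truth):
        rep = base_composition(truth.genome_m1)
        assert sum(rep.percentages.values()) == pytest.approx(100.0, abs=0.01)

    def test_all_n_errors(self):
        with pytest.raises(Exception):
            base_composition("NNN")

    def test_simulated_heavy_strand_is_g_poor(self, truth):
        # the generator bakes in the vertebrate heavy-strand G deficit
        for g in (truth.genome_m1, truth.genome_m2):
            assert base_composition(g).guanine_pct_heavy < 20.0


class TestTranslation:
    def test_tga_is_tryptophan(self):
        # vertebrate mito code: TGA = Trp, not stop
        genome = MitoGenome("g", "ATGTGATAA", circular=False,
                            annotations=[GeneAnnotation("x", "CDS", 0, 9)])
        rep = translate_cds(genome)
        assert rep.per_cds[0].protein == "MW"
        assert not rep.per_cds[0].internal_stop_positions

    def test_aga_is_internal_stop(self):
        genome = MitoGenome("g", "ATGAGAAAATAA", circular=False,
                            annotations=[GeneAnnotation("x", "CDS", 0, 12)])
        rep = translate_cds(genome)
        assert rep.per_cds[0].internal_stop_positions == [1]
        assert not rep.passed

    def test_incomplete_stop_flagged_not_failed(self):
        genome = MitoGenome("g", "ATGAAAACCT", circular=False,
                            annotations=[GeneAnnotation("x", "CDS", 0, 10)])
        rep = translate_cds(genome)
        cds = rep.per_cds[0]
        assert not cds.stop_complete and cds.stop_codon == "T"
        assert rep.passed

    def test_strand_respects_reading_orientation(self):
        orf = "ATGTGATGCTAA"
        genome = MitoGenome(
            "g", reverse_complement(orf), circular=False,
            annotations=[GeneAnnotation("x", "CDS", 0, 12, "light")])
        heavy = MitoGenome("h", orf, circular=False,
                           annotations=[GeneAnnotation("x", "CDS", 0, 12)])
        assert translate_cds(genome).per_cds[0].protein == \
            translate_cds(heavy).per_cds[0].protein

    def test_simulated_genomes_all_cds_clean(self, truth):
        for g in (truth.genome_m1, truth.genome_m2):
            rep = translate_cds(g)
            assert len(rep.per_cds) == 13 and rep.passed


class TestFoldTrna:
    def test_template_cloverleafs_fold_with_anticodon(self, rng):
        for name, anticodon in ANTICODONS.items():
            seq = make_trna_sequence(rng, anticodon)
            st = fold_trna(seq)
            assert st.folded, name
            assert st.anticodon == anticodon, name
            assert not st.d_arm_replacement_loop

    def test_d_stem_scramble_yields_replacement_loop(self, rng):
        # destroy the D stem (positions 9-12 pair with 21-24 in the
        # template layout) and keep everything else: the fold must fall
        # back to a D-arm replacement loop, as in the unusual tRNA-Cys
        for _ in range(10):
            seq = make_trna_sequence(rng, "GCA")
            broken = list(seq)
            for i in range(9, 13):
                broken[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[24 - (i - 9)]]
            st = fold_trna("".join(broken))
            if st.folded and st.d_arm_replacement_loop:
                return
        pytest.fail("no D-arm replacement loop found in any trial")

    def test_random_sequences_mostly_fail(self, rng):
        fails = sum(
            not fold_trna("".join(rng.choice(list("ACGT"), size=70))).folded
            for _ in range(100)
        )
        assert fails >= 95

    def test_length_bounds_enforced(self):
        with pytest.raises(Exception):
            fold_trna("ACGT" * 10)  # 40 nt

    def test_evolved_genome_trnas_fold(self, truth):
        for g in (truth.genome_m1, truth.genome_m2):
            for ann in g.annotations:
                if ann.kind == "tRNA":
                    assert fold_trna(g.feature_sequence(ann)).folded, ann.name


class TestStemLoopScan:
    STEM = "GCCTACAGTCAC"  # 12 bp; 3' arm ends in the GGC motif
    LOOP = "TTTTTTTT"  # 8 nt

    def _genome_with_hairpin(self):
        """tRNA-Asn, a hairpin overlapping it by 14 bp, then tRNA-Cys
        overlapped by 2 bp (mirroring the unusual O_L arrangement)."""
        hairpin = self.STEM + self.LOOP + reverse_complement(self.STEM)
        pad = "C" * 80
        # tRNA-Asn ends 14 bases into the hairpin; tRNA-Cys starts 2 bases
        # before the hairpin ends
        start_hp = 80
        anns = [
            GeneAnnotation("trnN", "tRNA", start_hp - 58, start_hp + 14,
                           "light"),
            GeneAnnotation("trnC", "tRNA", start_hp + len(hairpin) - 2,
                           start_hp + len(hairpin) - 2 + 72, "light"),
        ]
        seq = pad + hairpin + "C" * 80
        return MitoGenome("g", seq, circular=False, annotations=anns)

    def test_perfect_inverted_repeat_single_hit(self):
        seq = "C" * 10 + self.STEM + self.LOOP + \
            reverse_complement(self.STEM) + "C" * 10
        hits = find_hairpins(seq)
        assert hits == [(10, 12, 8, 0)]

    def test_overlap_values_reported(self):
        genome = self._genome_with_hairpin()
        hits = scan_ol_stemloop(genome)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.stem_length == 12 and hit.loop_length == 8
        assert hit.overlap_upstream_trna == 14
        assert hit.overlap_downstream_trna == 2

    def test_elongation_motif_detected_at_stem_base(self):
        genome = self._genome_with_hairpin()
        hit = scan_ol_stemloop(genome)[0]
        # the 3' stem arm ends with the GGC heavy-strand triplet
        assert hit.elongation_motif_present

    def test_hairpin_free_window_empty(self):
        genome = MitoGenome("g", "ACTCAG" * 50, circular=False)
        assert scan_ol_stemloop(genome, window=(0, 200)) == []


class TestSiteClassFraction:
    def test_study_table_gives_78_percent(self):
        table = ([(i, "transmembrane", True) for i in range(43)]
                 + [(100 + i, "loop", True) for i in range(12)]
                 + [(200 + i, "loop", False) for i in range(45)])
        out = site_class_fraction(table)
        assert out.n_flagged == 55
        assert out.per_class_pct_of_flagged["transmembrane"] == 78

    def test_no_flags(self):
        out = site_class_fraction([(1, "loop", False), (2, "other", False)])
        assert out.n_flagged == 0
        assert set(out.per_class_pct_of_flagged.values()) == {0}

    def test_randomized_labels_track_base_rate(self, rng):
        classes = ["transmembrane"] * 300 + ["loop"] * 700
        rng.shuffle(classes)
        flagged = rng.random(1000) < 0.2
        table = [(i, c, bool(f)) for i, (c, f) in
                 enumerate(zip(classes, flagged))]
        out = site_class_fraction(table)
        assert abs(out.per_class_pct_of_flagged["transmembrane"] - 30) <= 10

    def test_empty_table_errors(self):
        with pytest.raises(Exception):
            site_class_fraction([])


def test_mito_translate_table_spot_checks():
    # ATA = Met and AGG = stop under the vertebrate mitochondrial code
    assert mito_translate("ATA") == "M"
    assert mito_translate("AGG") == "*"
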