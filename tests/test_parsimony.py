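import itertools

import numpy as np
import pytest

from mitotwin.io import MultipleAlignment
from mitotwin.parsimony import (
    ConcatRules,
    Tree,
    bootstrap,
    branch_and_bound_search,
    build_concatenation,
    count_informative_sites,
    decay_index,
    exhaustive_search,
    fitch_length,
    strict_consensus,
    templeton_test,
    tree_from_newick,
    tree_from_splits,
    whole_tree_decay,
)
from mitotwin.parsimony import test_monophyly as monophyly_comparison


def aln(**rows):
    return MultipleAlignment(names=list(rows), rows=list(rows.values()))


def random_alignment(rng, n_taxa, n_sites, gap_frac=0.05):
    p = [(1 - gap_frac) / 4] * 4 + [gap_frac]
    rows = ["".join(rng.choice(list("ACGT-"), size=n_sites, p=p))
            for _ in range(n_taxa)]
    return MultipleAlignment(names=[f"t{i}" for i in range(n_taxa)], rows=rows)


# ---------------------------------------------------------------------------
# independent oracles


def sankoff_unit_cost(tree: Tree, alignment: MultipleAlignment) -> int:
    """Unit-cost Sankoff dynamic programme (independent of the Fitch path).

    Missing characters (gap/N) contribute zero cost from any state.
    """
    states = "ACGT"
    idx = {name: i for i, name in enumerate(tree.leaf_names)}
    adj = {}
    for a, b in tree.edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    root = tree.edges[0][0]
    total = 0
    n = len(tree.leaf_names)
    for site in range(alignment.site_count):
        chars = {name: alignment.row(name)[site] for name in tree.leaf_names}

        def cost(node, parent):
            if node < n and not [k for k in adj[node] if k != parent]:
                c = chars[tree.leaf_names[node]]
                if c in "-N?":
                    return [0.0] * 4
                return [0.0 if s == c else float("inf") for s in states]
            kid_costs = [cost(k, node) for k in adj[node] if k != parent]
            own = [0.0] * 4
            if node < n:  # leaf used as traversal root
                c = chars[tree.leaf_names[node]]
                if c not in "-N?":
                    own = [0.0 if s == c else float("inf") for s in states]
            out = []
            for s in range(4):
                acc = own[s]
                for kc in kid_costs:
                    acc += min(kc[t] + (0 if t == s else 1) for t in range(4))
                out.append(acc)
            return out

        best = min(cost(root, -1))
        if best != float("inf"):
            total += int(best)
    return total


def brute_force_informative(alignment: MultipleAlignment) -> int:
    from collections import Counter

    n = 0
    for i in range(alignment.site_count):
        col = Counter(
            r[i] for r in alignment.rows if r[i] not in "-N?")
        if len([c for c in col.values() if c >= 2]) >= 2:
            n += 1
    return n


# ---------------------------------------------------------------------------


class TestFitch:
    def test_textbook_four_taxon_site(self):
        a = aln(t1="A", t2="A", t3="G", t4="G")
        good = tree_from_splits(("t1", "t2", "t3", "t4"),
                                [frozenset({"t1", "t2"})])
        bad = tree_from_splits(("t1", "t2", "t3", "t4"),
                               [frozenset({"t1", "t3"})])
        assert fitch_length(good, a)[0] == 1
        assert fitch_length(bad, a)[0] == 2

    def test_invariant_site_zero_steps(self):
        a = aln(t1="AAAA", t2="AAAA", t3="AAAA", t4="AAAA")
        t = tree_from_splits(tuple(a.names), [frozenset({"t1", "t2"})])
        assert fitch_length(t, a)[0] == 0

    def test_additivity_total_equals_site_sum(self, rng):
        a = random_alignment(rng, 6, 40)
        t = exhaustive_search(a).shortest_trees[0]
        total, per_site = fitch_length(t, a)
        assert total == per_site.sum()

    def test_matches_unit_cost_sankoff(self, rng):
        """Oracle equivalence on random 6-taxon instances."""
        for _ in range(10):
            a = random_alignment(rng, 6, 12)
            t = exhaustive_search(a).shortest_trees[0]
            assert fitch_length(t, a)[0] == sankoff_unit_cost(t, a)


class TestInformativeSites:
    def test_invariant_alignment_zero(self):
        a = aln(t1="AAAA", t2="AAAA", t3="AAAA", t4="AAAA")
        assert count_informative_sites(a) == 0

    def test_single_aabb_site(self):
        a = aln(t1="A", t2="A", t3="G", t4="G")
        assert count_informative_sites(a) == 1

    def test_matches_per_site_brute_force(self, rng):
        for _ in range(5):
            a = random_alignment(rng, 7, 60, gap_frac=0.15)
            assert count_informative_sites(a) == brute_force_informative(a)


class TestBranchAndBound:
    def test_repeated_aabb_pattern_unique_shortest(self):
        a = aln(t1="AAAAA", t2="AAAAA", t3="GGGGG", t4="GGGGG")
        res = branch_and_bound_search(a)
        assert len(res.shortest_trees) == 1
        assert res.shortest_trees[0].has_clade({"t1", "t2"})
        assert res.length == 5

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_equals_exhaustive_enumeration(self, rng, n_taxa):
        for _ in range(3):
            a = random_alignment(rng, n_taxa, 15)
            bb = branch_and_bound_search(a)
            ex = exhaustive_search(a)
            assert bb.length == ex.length
            assert {t.splits() for t in bb.shortest_trees} == \
                {t.splits() for t in ex.shortest_trees}

    def test_taxa_guard(self, rng):
        a = random_alignment(rng, 17, 10)
        with pytest.raises(Exception, match="heuristic|guard|taxa"):
            branch_and_bound_search(a)

    def test_constrained_length_never_shorter(self, rng):
        for _ in range(5):
            a = random_alignment(rng, 6, 20)
            free = branch_and_bound_search(a)
            constraint = tree_from_splits(
                tuple(sorted(a.names)), [frozenset({"t0", "t1"})])
            constrained = branch_and_bound_search(a, constraint=constraint)
            assert constrained.length >= free.length


class TestBootstrap:
    def test_clean_signal_high_support(self, rng):
        # 20 consistent informative sites splitting {a,b} from {c,d,e}
        rows = {"a": "A" * 20, "b": "A" * 20, "c": "G" * 20,
                "d": "G" * 20, "e": "G" * 20}
        noise = {"a": "ACGTA", "b": "CAGTT", "c": "GTACG",
                 "d": "TACGA", "e": "AGCTA"}
        a = MultipleAlignment(names=list(rows),
                              rows=[rows[k] + noise[k] for k in rows])
        support = bootstrap(a, replicates=100, seed=5)
        key = frozenset({"a", "b"})
        assert support.get(key, 0.0) >= 95.0

    def test_deterministic_given_seed(self, rng):
        a = random_alignment(rng, 5, 30)
        s1 = bootstrap(a, replicates=30, seed=11)
        s2 = bootstrap(a, replicates=30, seed=11)
        assert s1 == s2

    def test_invariant_alignment_no_strong_split(self):
        a = aln(t1="AAAAAAAAAA", t2="AAAAAAAAAA", t3="AAAAAAAAAA",
                t4="AAAAAAAAAA", t5="AAAAAAAAAA")
        support = bootstrap(a, replicates=30, seed=2)
        # a star signal: any resolved split is a tie artifact, never fixed
        assert all(v < 50.0 for v in support.values()) or not support


class TestDecay:
    def test_k_uncontradicted_sites_give_decay_k(self):
        for k in (2, 5):
            sites = {"a": "A" * k, "b": "A" * k, "c": "G" * k, "d": "G" * k,
                     "e": "G" * k}
            a = MultipleAlignment(names=list(sites),
                                  rows=list(sites.values()))
            assert decay_index(a, {"a", "b"}) == k

    def test_unsupported_clade_zero(self, rng):
        a = aln(t1="AAAA", t2="AAAA", t3="AAAA", t4="AAAA", t5="AAAA")
        assert decay_index(a, {"t1", "t2"}) == 0

    def test_whole_tree_collapse_is_min_over_splits(self):
        sites = {"a": "AAAA" + "CC", "b": "AAAA" + "CC", "c": "GGGG" + "CC",
                 "d": "GGGG" + "TT", "e": "GGGG" + "TT"}
        a = MultipleAlignment(names=list(sites), rows=list(sites.values()))
        res = branch_and_bound_search(a)
        splits = strict_consensus(res.shortest_trees).splits()
        decays = [decay_index(a, s, unconstrained=res) for s in splits]
        assert whole_tree_decay(a, res) == min(decays)


class TestTempleton:
    def trees_4taxa(self):
        names = ("t0", "t1", "t2", "t3")
        ta = tree_from_splits(names, [frozenset({"t0", "t1"})])
        tb = tree_from_splits(names, [frozenset({"t0", "t2"})])
        return ta, tb

    def test_same_tree_p_one(self, rng):
        a = random_alignment(rng, 4, 30)
        ta, _ = self.trees_4taxa()
        res = templeton_test(a, ta, ta)
        assert res.p_two_tailed == 1.0 and res.no_difference

    def test_ten_unanimous_sites_exact_p(self):
        # 10 informative sites all favouring t0t1|t2t3: exact two-tailed
        # p = 2 * (1/2)^10
        a = aln(t0="A" * 10, t1="A" * 10, t2="G" * 10, t3="G" * 10)
        ta, tb = self.trees_4taxa()
        res = templeton_test(a, ta, tb)
        assert res.n_differing_sites == 10
        assert res.p_two_tailed == pytest.approx(2 / 2**10)

    def test_symmetry_negates_z(self, rng):
        a = random_alignment(rng, 4, 60, gap_frac=0.0)
        ta, tb = self.trees_4taxa()
        r1 = templeton_test(a, ta, tb)
        r2 = templeton_test(a, tb, ta)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    def test_matches_sign_permutation_brute_force(self, rng):
        """Exact p against a literal 2^n enumeration for n <= 12."""
        for trial in range(5):
            a = random_alignment(rng, 4, 30, gap_frac=0.0)
            ta, tb = self.trees_4taxa()
            _, sa = fitch_length(ta, a)
            _, sb = fitch_length(tb, a)
            diffs = (sa - sb).astype(float)
            diffs = diffs[diffs != 0]
            n = len(diffs)
            if n == 0 or n > 12:
                continue
            res = templeton_test(a, ta, tb)
            # midranks of |d|
            absd = np.abs(diffs)
            order = np.argsort(absd, kind="stable")
            ranks = np.empty(n)
            sorted_abs = absd[order]
            i = 0
            while i < n:
                j = i
                while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
                    j += 1
                for k in range(i, j + 1):
                    ranks[order[k]] = (i + j) / 2 + 1
                i = j + 1
            t_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
            hits = 0
            for signs in itertools.product([0, 1], repeat=n):
                tp = sum(r for r, s in zip(ranks, signs) if s)
                if min(tp, ranks.sum() - tp) <= t_obs + 1e-9:
                    hits += 1
            assert res.p_two_tailed == pytest.approx(hits / 2**n)

    def test_z_matches_scipy_tie_corrected(self, rng):
        from scipy.stats import wilcoxon

        for _ in range(5):
            a = random_alignment(rng, 4, 300, gap_frac=0.0)
            ta, tb = self.trees_4taxa()
            _, sa = fitch_length(ta, a)
            _, sb = fitch_length(tb, a)
            diffs = (sa - sb).astype(float)
            diffs = diffs[diffs != 0]
            if len(diffs) <= 20:
                continue
            res = templeton_test(a, ta, tb)
            ref = wilcoxon(diffs, correction=False, method="approx")
            assert abs(res.z) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
            assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-9)


class TestMonophylyAndConsensus:
    def test_already_monophyletic_group_costs_nothing(self):
        a = aln(a="AAAAA", b="AAAAA", c="GGGGG", d="GGGGG")
        free, constrained, temp, diff = monophyly_comparison(a, ["a", "b"])
        assert diff == 0 and temp.p_two_tailed == 1.0

    def test_constraint_monotonicity(self, rng):
        for _ in range(3):
            a = random_alignment(rng, 6, 25)
            free, constrained, _, diff = monophyly_comparison(a, ["t0", "t3"])
            assert diff >= 0

    def test_strict_consensus_single_tree_identity(self, rng):
        a = random_alignment(rng, 6, 30)
        t = branch_and_bound_search(a).shortest_trees[0]
        assert strict_consensus([t]).splits() == t.splits()

    def test_conflicting_split_collapses(self):
        names = ("a", "b", "c", "d", "e")
        t1 = tree_from_splits(names, [frozenset({"a", "b"}),
                                      frozenset({"d", "e"})])
        t2 = tree_from_splits(names, [frozenset({"a", "b"}),
                                      frozenset({"c", "d"})])
        cons = strict_consensus([t1, t2])
        assert cons.splits() == frozenset({frozenset({"a", "b"})})

    def test_consensus_splits_subset_of_inputs(self, rng):
        a = random_alignment(rng, 7, 12)
        trees = branch_and_bound_search(a).shortest_trees
        cons = strict_consensus(trees)
        for t in trees:
            assert cons.splits() <= t.splits()

    def test_newick_round_trip(self, rng):
        a = random_alignment(rng, 6, 30)
        t = branch_and_bound_search(a).shortest_trees[0]
        back = tree_from_newick(t.newick())
        assert back.splits() == t.splits()


class TestConcatenation:
    def _two_genomes(self, truth):
        return {"M1": truth.genome_m1, "M2": truth.genome_m2}

    def test_identical_genomes_gapless_sum_of_lengths(self, truth):
        genomes = {"A": truth.genome_m1, "B": truth.genome_m1}
        genes = ["ATP8", "ND4L", "ND3"]
        out, prov = build_concatenation(genomes, genes)
        lengths = {a.name: a.length for a in truth.genome_m1.annotations}
        expected = (lengths["ATP8"] - 96) + (lengths["ND4L"] - 7) + lengths["ND3"]
        assert out.site_count == expected
        assert all("-" not in row for row in out.rows)

    def test_excluded_gene_dropped(self, truth):
        out, prov = build_concatenation(
            self._two_genomes(truth), ["ND5", "ND3"])
        assert "ND5" not in prov and "ND3" in prov

    def test_atp8_tail_exclusion_exact(self, truth):
        genomes = self._two_genomes(truth)
        with_rule, _ = build_concatenation(genomes, ["ATP8"])
        without, _ = build_concatenation(
            genomes, ["ATP8"], ConcatRules(exclude_tail=()))
        assert without.site_count - with_rule.site_count == 96

    def test_stated_gap_insertions_pad_shorter_rows(self):
        """A row 7 codons longer stays intact; shorter rows receive 15 + 6
        gap columns at the stated offsets."""
        from mitotwin.io import GeneAnnotation, MitoGenome

        short = "ATG" + "AAC" * 300 + "TAA"  # 302 codons
        long_ = "ATG" + "AAC" * 307 + "TAA"  # 7 codons longer
        g_short = MitoGenome("s", short, circular=False, annotations=[
            GeneAnnotation("Cytb", "CDS", 0, len(short))])
        g_long = MitoGenome("l", long_, circular=False, annotations=[
            GeneAnnotation("Cytb", "CDS", 0, len(long_))])
        rules = ConcatRules(exclude_genes=(), exclude_tail=(),
                            gap_insertions=(("Cytb", 9, 15), ("Cytb", 873, 6)))
        out, _ = build_concatenation({"s": g_short, "l": g_long},
                                     ["Cytb"], rules)
        row_s = out.row("s")
        assert "-" not in out.row("l")
        assert row_s[9:24] == "-" * 15
        assert row_s[873 + 15:873 + 15 + 6] == "-" * 6
        assert out.site_count == len(long_)

    def test_missing_gene_named_in_error(self, truth):
        genomes = {"M1": truth.genome_m1}
        from mitotwin.io import MitoGenome

        bare = MitoGenome("bare", "ACGTACGT" * 10, circular=False)
        genomes["bare"] = bare
        with pytest.raises(Exception, match="bare.*ND3|ND3.*bare"):
            build_concatenation(genomes, ["ND3"])
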