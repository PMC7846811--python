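"""Maximum-parsimony inference and paired-sites hypothesis testing.

Implements exact branch-and-bound search over unrooted binary topologies
with Fitch (unordered, unit-cost) optimization, gaps and N as missing data;
nonparametric bootstrap; Bremer decay indices via reverse-constraint
searches; Templeton two-tailed Wilcoxon signed-ranks comparisons of trees
(tie-corrected normal approximation, exact for few differing sites); and
strict consensus.  Desk-scale by design: searches are exact and guarded to
at most 16 taxa.

Trees are unrooted; a topology is identified by its set of non-trivial
splits (bipartitions of the leaf set).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import MultipleAlignment, ValidationError

# ---------------------------------------------------------------------------
# tree representation
#
# Internally a topology over leaves 0..n-1 is a list of edges between node
# ids (leaves 0..n-1, internal >= n).  Public results carry leaf names and
# newick serialization.

_STATE = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15, "-": 15, "?": 15}
_MISSING = 15


@dataclass
class Tree:
    """Unrooted binary tree over named leaves, stored as parent arrays of an
    arbitrary rooting plus the derived split set."""

    leaf_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._splits: Optional[frozenset[frozenset[str]]] = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each as the frozenset of leaf names on the
        smaller-or-lexicographic side."""
        if self._splits is not None:
            return self._splits
        n = self.n_leaves
        adj: dict[int, list[int]] = {}
        for a, b in self.edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        all_names = frozenset(self.leaf_names)
        splits = set()
        def below(child: int, parent: int) -> frozenset:
            """Leaf names on the child side of the (parent, child) edge."""
            def rec(c, p):
                acc = set()
                if c < n:
                    acc.add(self.leaf_names[c])
                for nb in adj[c]:
                    if nb != p:
                        acc |= rec(nb, c)
                return acc

            return frozenset(rec(child, parent))

        for a, b in self.edges:
            side = below(b, a)
            if 1 < len(side) < n - 1:
                other = all_names - side
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        self._splits = frozenset(splits)
        return self._splits

    def has_clade(self, group: Iterable[str]) -> bool:
        g = frozenset(group)
        comp = frozenset(self.leaf_names) - g
        key = min(g, comp, key=lambda s: (len(s), sorted(s)))
        if len(g) <= 1 or len(comp) <= 1:
            return True  # trivial
        return key in self.splits()

    def newick(self) -> str:
        n = self.n_leaves
        adj: dict[int, list[int]] = {}
        for a, b in self.edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        root = 0  # display-root at first leaf's neighbour

        def sub(c: int, p: int) -> str:
            kids = [nb for nb in adj[c] if nb != p]
            if not kids:
                return self.leaf_names[c]
            inner = ",".join(sub(k, c) for k in kids)
            return f"({inner})"

        anchor = adj[root][0]
        parts = [self.leaf_names[root]] + [
            sub(k, anchor) for k in adj[anchor] if k != root
        ]
        return "(" + ",".join(parts) + ");"

    def __eq__(self, other) -> bool:
        return (isinstance(other, Tree)
                and set(self.leaf_names) == set(other.leaf_names)
                and self.splits() == other.splits())

    def __hash__(self) -> int:
        return hash((frozenset(self.leaf_names), self.splits()))


def tree_from_newick(text: str) -> Tree:
    """Parse a newick string into an unrooted Tree (topology only)."""
    import dendropy

    t = dendropy.Tree.get(data=text, schema="newick")
    t.deroot()
    names = tuple(sorted(lf.taxon.label for lf in t.leaf_node_iter()))
    index = {name: i for i, name in enumerate(names)}
    edges = []
    next_id = [len(names)]
    node_ids: dict = {}

    def nid(node):
        if node not in node_ids:
            if node.is_leaf():
                node_ids[node] = index[node.taxon.label]
            else:
                node_ids[node] = next_id[0]
                next_id[0] += 1
        return node_ids[node]

    for edge in t.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        edges.append((nid(edge.tail_node), nid(edge.head_node)))
    return Tree(leaf_names=names, edges=tuple(edges))


# ---------------------------------------------------------------------------
# alignment encoding and Fitch optimization


def encode_alignment(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Collapse alignment columns to unique site patterns.

    Returns (patterns[n_taxa, n_patterns] of state bitmasks, weights,
    taxon names).
    """
    mat = np.array(
        [[_STATE.get(c, _MISSING) for c in row] for row in aln.rows],
        dtype=np.uint8,
    )
    patterns, inverse = np.unique(mat, axis=1, return_inverse=True)
    weights = np.bincount(inverse, minlength=patterns.shape[1])
    return patterns, weights.astype(np.int64), list(aln.names)


def count_informative_sites(aln: MultipleAlignment) -> int:
    """Sites with >= 2 states, each present in >= 2 rows (gap/N missing)."""
    count = 0
    for col in zip(*aln.rows):
        states = [c for c in col if c not in "-N?"]
        tally: dict[str, int] = {}
        for c in states:
            tally[c] = tally.get(c, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


def _postorder(edges: Sequence[tuple[int, int]], n_leaves: int,
               root: int) -> list[tuple[int, list[int]]]:
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    order = []
    stack = [(root, -1)]
    visit = []
    while stack:
        node, parent = stack.pop()
        kids = [nb for nb in adj.get(node, []) if nb != parent]
        visit.append((node, kids))
        for k in kids:
            stack.append((k, node))
    visit.reverse()
    return visit


def fitch_length(tree: Tree, aln: MultipleAlignment
                 ) -> tuple[int, np.ndarray]:
    """Fitch step count of a tree on an alignment.

    Returns (total steps, per-site steps for the original columns).
    Gaps and N are missing data and never contribute steps.
    """
    missing = set(aln.names) - set(tree.leaf_names)
    extra = set(tree.leaf_names) - set(aln.names)
    if extra:
        raise ValidationError(f"tree leaves missing from alignment: {sorted(extra)}")
    mat = np.array(
        [[_STATE.get(c, _MISSING) for c in aln.row(name)]
         for name in tree.leaf_names],
        dtype=np.uint8,
    )
    per_site = _fitch_steps_edges(tree.edges, tree.n_leaves, mat)
    return int(per_site.sum()), per_site


def _fitch_steps_edges(edges: Sequence[tuple[int, int]], n_leaves: int,
                       leaf_states: np.ndarray,
                       weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized Fitch pass over all sites; returns per-site (or weighted
    total if weights given) step counts."""
    max_node = max(max(e) for e in edges) + 1
    n_sites = leaf_states.shape[1]
    states = np.zeros((max_node, n_sites), dtype=np.uint8)
    states[:n_leaves] = leaf_states
    steps = np.zeros(n_sites, dtype=np.int64)
    root = edges[0][0]
    for node, kids in _postorder(edges, n_leaves, root):
        if not kids:
            continue
        if node < n_leaves:  # a leaf used as traversal root keeps its state
            acc = states[node].copy()
            rest = kids
        else:
            acc = states[kids[0]].copy()
            rest = kids[1:]
        for k in rest:
            inter = acc & states[k]
            union = acc | states[k]
            empty = inter == 0
            steps += empty
            acc = np.where(empty, union, inter)
        states[node] = acc
    if weights is not None:
        return steps @ weights
    return steps


# ---------------------------------------------------------------------------
# exact searches


@dataclass
class ParsimonyResult:
    shortest_trees: list[Tree]
    length: int
    n_sites: int
    n_parsimony_informative: int
    bootstrap_support: dict[frozenset, float] = field(default_factory=dict)
    decay_indices: dict[frozenset, int] = field(default_factory=dict)

    @property
    def strict(self) -> Tree:
        return strict_consensus(self.shortest_trees)


def _addition_order(patterns: np.ndarray, weights: np.ndarray) -> list[int]:
    """Taxa sorted by decreasing mismatch distance to taxon 0 (tight bounds
    early); taxon 0 stays first."""
    n = patterns.shape[0]
    d = [
        int(((patterns[0] & patterns[i]) == 0) @ weights)
        for i in range(n)
    ]
    rest = sorted(range(1, n), key=lambda i: -d[i])
    return [0] + rest


def _enumerate_edges(order: list[int], n: int):
    """Yield complete edge lists by stepwise taxon insertion (generator used
    by the exhaustive oracle in tests)."""
    def rec(edges, next_internal, k):
        if k == len(order):
            yield list(edges)
            return
        taxon = order[k]
        for idx in range(len(edges)):
            a, b = edges[idx]
            mid = next_internal
            new_edges = (edges[:idx]
                         + [(a, mid), (mid, b), (mid, taxon)]
                         + edges[idx + 1:])
            yield from rec(new_edges, next_internal + 1, k + 1)

    if len(order) < 3:
        raise ValidationError("need >= 3 taxa")
    base = [(order[0], n), (n, order[1]), (n, order[2])]
    yield from rec(base, n + 1, 3)


def branch_and_bound_search(aln: MultipleAlignment,
                            constraint: Optional["Tree"] = None,
                            require_incompatible_with: Optional[frozenset] = None,
                            max_taxa: int = 16) -> ParsimonyResult:
    """Exact search for all minimum-length trees.

    Stepwise addition with pruning: a partial tree's length never decreases
    as taxa are added, so any partial tree longer than the best complete
    tree found so far is abandoned.  ``constraint`` restricts the result to
    trees compatible with (containing all non-trivial splits of) the given
    tree; ``require_incompatible_with`` restricts to trees NOT containing
    the given clade (used for decay indices).
    """
    n = len(aln.names)
    if n < 4:
        raise ValidationError("need >= 4 taxa for an unrooted search")
    if n > max_taxa:
        raise ValidationError(
            f"{n} taxa exceeds the exact-search guard ({max_taxa}); "
            "use a heuristic tool for larger problems"
        )
    patterns, weights, names = encode_alignment(aln)
    order = _addition_order(patterns, weights)

    constraint_splits: Optional[set[frozenset]] = None
    if constraint is not None:
        constraint_splits = set(constraint.splits())
    forbidden = require_incompatible_with

    best_len = [np.iinfo(np.int64).max]
    best_edges: list[list[tuple[int, int]]] = []

    def tree_ok(edges) -> bool:
        t = Tree(leaf_names=tuple(names), edges=tuple(edges))
        if constraint_splits is not None and not constraint_splits <= set(t.splits()):
            return False
        if forbidden is not None and t.has_clade(forbidden):
            return False
        return True

    def rec(edges, next_internal, k):
        length = int(_fitch_steps_edges(edges, n, patterns, weights))
        if length > best_len[0]:
            return
        if k == len(order):
            if not tree_ok(edges):
                return
            if length < best_len[0]:
                best_len[0] = length
                best_edges.clear()
            if length == best_len[0]:
                best_edges.append(list(edges))
            return
        taxon = order[k]
        for idx in range(len(edges)):
            a, b = edges[idx]
            mid = next_internal
            new_edges = (edges[:idx]
                         + [(a, mid), (mid, b), (mid, taxon)]
                         + edges[idx + 1:])
            rec(new_edges, next_internal + 1, k + 1)

    base = [(order[0], n), (n, order[1]), (n, order[2])]
    rec(base, n + 1, 3)

    if not best_edges:
        raise ValidationError("no tree satisfies the constraint")
    trees = [Tree(leaf_names=tuple(names), edges=tuple(e)) for e in best_edges]
    # deduplicate by topology
    uniq: dict = {}
    for t in trees:
        uniq.setdefault(t.splits(), t)
    return ParsimonyResult(
        shortest_trees=list(uniq.values()),
        length=int(best_len[0]),
        n_sites=aln.site_count,
        n_parsimony_informative=count_informative_sites(aln),
    )


def exhaustive_search(aln: MultipleAlignment) -> ParsimonyResult:
    """Plain enumeration of every unrooted topology (oracle for tests)."""
    n = len(aln.names)
    patterns, weights, names = encode_alignment(aln)
    order = list(range(n))
    best_len = None
    best = []
    for edges in _enumerate_edges(order, n):
        length = int(_fitch_steps_edges(edges, n, patterns, weights))
        if best_len is None or length < best_len:
            best_len = length
            best = [edges]
        elif length == best_len:
            best.append(edges)
    trees = [Tree(leaf_names=tuple(names), edges=tuple(e)) for e in best]
    uniq: dict = {}
    for t in trees:
        uniq.setdefault(t.splits(), t)
    return ParsimonyResult(
        shortest_trees=list(uniq.values()), length=int(best_len),
        n_sites=aln.site_count,
        n_parsimony_informative=count_informative_sites(aln),
    )


# ---------------------------------------------------------------------------
# support measures


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValidationError("no trees")
    leaf_sets = {frozenset(t.leaf_names) for t in trees}
    if len(leaf_sets) != 1:
        raise ValidationError("trees are on different leaf sets")
    common = set(trees[0].splits())
    for t in trees[1:]:
        common &= set(t.splits())
    return tree_from_splits(tuple(sorted(trees[0].leaf_names)), common)


def tree_from_splits(leaf_names: tuple[str, ...],
                     splits: Iterable[frozenset]) -> Tree:
    """Build a (possibly multifurcating) tree realizing compatible splits."""
    names = tuple(leaf_names)
    index = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    all_set = frozenset(names)
    # normalize to the side not containing leaf 0, sort big-to-small (nesting)
    norm = []
    for s in splits:
        side = s if names[0] not in s else all_set - s
        norm.append(frozenset(side))
    norm = sorted(set(norm), key=len, reverse=True)
    parent_group: dict[frozenset, frozenset] = {}
    children: dict[frozenset, list] = {all_set: []}
    for s in norm:
        host = all_set
        for t in norm:
            if t != s and s < t and (host == all_set or len(t) < len(host)):
                host = t
        children.setdefault(s, [])
        children[host].append(s)
    # leaves attach to the smallest group containing them
    leaf_host: dict[str, frozenset] = {}
    for nm in names:
        host = all_set
        for s in norm:
            if nm in s and len(s) < len(host):
                host = s
        leaf_host[nm] = host
    edges = []
    next_id = [n]
    group_id: dict[frozenset, int] = {}

    def gid(g):
        if g not in group_id:
            group_id[g] = next_id[0]
            next_id[0] += 1
        return group_id[g]

    for g, kids in children.items():
        for k in kids:
            edges.append((gid(g), gid(k)))
    for nm in names:
        edges.append((gid(leaf_host[nm]), index[nm]))
    return Tree(leaf_names=names, edges=tuple(edges))


def bootstrap(aln: MultipleAlignment, replicates: int = 100,
              seed: int = 0, max_taxa: int = 16) -> dict[frozenset, float]:
    """Nonparametric bootstrap support for splits.

    Sites are resampled with replacement; each replicate is searched exactly
    and a split is credited when it appears in the strict consensus of that
    replicate's shortest trees.  Returns split -> percent support.
    """
    if replicates < 1:
        raise ValidationError("need >= 1 replicate")
    rng = np.random.default_rng(seed % (2**31))
    counts: dict[frozenset, int] = {}
    n_sites = aln.site_count
    for _ in range(replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = MultipleAlignment(
            names=list(aln.names),
            rows=["".join(row[i] for i in idx) for row in aln.rows],
        )
        res = branch_and_bound_search(rep, max_taxa=max_taxa)
        for split in strict_consensus(res.shortest_trees).splits():
            counts[split] = counts.get(split, 0) + 1
    return {s: 100.0 * c / replicates for s, c in counts.items()}


def decay_index(aln: MultipleAlignment, clade: Iterable[str],
                unconstrained: Optional[ParsimonyResult] = None,
                max_taxa: int = 16) -> int:
    """Bremer support: extra steps of the best tree lacking the clade."""
    group = frozenset(clade)
    if unconstrained is None:
        unconstrained = branch_and_bound_search(aln, max_taxa=max_taxa)
    anti = branch_and_bound_search(
        aln, require_incompatible_with=group, max_taxa=max_taxa)
    return anti.length - unconstrained.length


def whole_tree_decay(aln: MultipleAlignment,
                     result: Optional[ParsimonyResult] = None,
                     max_taxa: int = 16) -> int:
    """Steps at which the entire tree collapses: min decay over the strict
    consensus splits."""
    if result is None:
        result = branch_and_bound_search(aln, max_taxa=max_taxa)
    splits = strict_consensus(result.shortest_trees).splits()
    if not splits:
        return 0
    return min(
        decay_index(aln, s, unconstrained=result, max_taxa=max_taxa)
        for s in splits
    )


# ---------------------------------------------------------------------------
# Templeton (Wilcoxon signed-ranks) test


@dataclass
class TempletonResult:
    n_differing_sites: int
    t_plus: float
    t_minus: float
    z: float
    p_two_tailed: float
    exact: bool
    no_difference: bool = False


def _signed_rank_stats(diffs: np.ndarray) -> tuple[float, float, np.ndarray]:
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(diffs))
    sorted_abs = absd[order]
    i = 0
    while i < len(diffs):
        j = i
        while j + 1 < len(diffs) and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    t_plus = float(ranks[diffs > 0].sum())
    t_minus = float(ranks[diffs < 0].sum())
    return t_plus, t_minus, ranks


def templeton_test(aln: MultipleAlignment, tree_a: Tree, tree_b: Tree,
                   exact_limit: int = 20) -> TempletonResult:
    """Two-tailed Wilcoxon signed-ranks comparison of two trees.

    Per-site Fitch step differences; zero differences dropped; midranks for
    tied |differences|; tie-corrected normal approximation, or the exact
    sign-permutation distribution when the number of differing sites is at
    most ``exact_limit``.
    """
    if set(tree_a.leaf_names) != set(tree_b.leaf_names):
        raise ValidationError("trees must share a leaf set")
    _, steps_a = fitch_length(tree_a, aln)
    _, steps_b = fitch_length(tree_b, aln)
    diffs = (steps_a - steps_b).astype(float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return TempletonResult(0, 0.0, 0.0, 0.0, 1.0, exact=True,
                               no_difference=True)
    t_plus, t_minus, ranks = _signed_rank_stats(diffs)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if var <= 0 else float((t_plus - mu) / np.sqrt(var))

    if n <= exact_limit:
        # exact sign-permutation distribution of T+ (midranks doubled so
        # every achievable sum is an integer)
        scaled = np.rint(ranks * 2).astype(int)
        total = int(scaled.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        dist /= 2.0**n
        obs = min(round(t_plus * 2), round(t_minus * 2))
        sums = np.arange(total + 1)
        extreme = np.minimum(sums, total - sums) <= obs
        p = float(min(1.0, dist[extreme].sum()))
        return TempletonResult(n, t_plus, t_minus, z, p, exact=True)
    from scipy.stats import norm as _norm

    p = float(min(1.0, 2.0 * _norm.sf(abs(z))))
    return TempletonResult(n, t_plus, t_minus, z, p, exact=False)


def test_monophyly(aln: MultipleAlignment, group: Iterable[str],
                   max_taxa: int = 16) -> tuple[ParsimonyResult, ParsimonyResult, TempletonResult, int]:
    """Constrained-monophyly comparison against the unconstrained best.

    Returns (unconstrained result, constrained result, Templeton comparison
    of the two best trees, step difference).
    """
    group = frozenset(group)
    if len(group) < 2:
        raise ValidationError("group must contain >= 2 leaves")
    names = tuple(sorted(aln.names))
    constraint = tree_from_splits(names, [group])
    free = branch_and_bound_search(aln, max_taxa=max_taxa)
    constrained = branch_and_bound_search(aln, constraint=constraint,
                                          max_taxa=max_taxa)
    temp = templeton_test(aln, constrained.shortest_trees[0],
                          free.shortest_trees[0])
    return free, constrained, temp, constrained.length - free.length


# ---------------------------------------------------------------------------
# concatenated-alignment construction


@dataclass
class ConcatRules:
    """Exclusion and gap rules applied when concatenating gene alignments.

    ``exclude_genes`` are dropped entirely (a gene absent from some source
    datasets cannot be compared).  ``exclude_tail`` drops the last k
    nucleotides of a gene, removing bicistronic overlaps with the downstream
    gene.  ``gap_insertions`` handle known length differences: for each
    (gene, nt_offset, n_gaps), every row shorter than that gene's longest
    row receives ``n_gaps`` gap columns after ``nt_offset`` nucleotides.
    """

    exclude_genes: tuple[str, ...] = ("ND5",)
    exclude_tail: tuple[tuple[str, int], ...] = (("ATP8", 96), ("ND4L", 7))
    gap_insertions: tuple[tuple[str, int, int], ...] = ()


def build_concatenation(genomes: dict, gene_set: Sequence[str],
                        rules: Optional[ConcatRules] = None
                        ) -> tuple[MultipleAlignment, dict[str, tuple[int, int]]]:
    """Concatenate per-gene alignments across genomes in a fixed gene order.

    Genes are extracted via each genome's annotations (light-strand genes in
    reading orientation).  Equal-length gene sets concatenate directly;
    unequal lengths go through the package's progressive aligner.  Returns
    the alignment and a provenance map gene -> (start, end) columns.

    Raises a named error when a requested gene is missing from a genome.
    """
    from .divergence import align_small_set

    rules = rules or ConcatRules()
    tails = dict(rules.exclude_tail)
    names = list(genomes.keys())
    parts: dict[str, list[str]] = {n: [] for n in names}
    provenance: dict[str, tuple[int, int]] = {}
    col = 0
    for gene in gene_set:
        if gene in rules.exclude_genes:
            continue
        seqs = []
        for name in names:
            genome = genomes[name]
            try:
                ann = genome.get_annotation(gene)
            except KeyError:
                raise ValidationError(
                    f"genome {name!r} lacks gene {gene!r}") from None
            seqs.append(genome.feature_sequence(ann))
        # stated gap insertions for rows shorter than the longest
        ins = [(off, k) for g, off, k in rules.gap_insertions if g == gene]
        if ins:
            longest = max(len(s) for s in seqs)
            padded = []
            for s in seqs:
                if len(s) < longest:
                    for off, k in sorted(ins, reverse=True):
                        s = s[:off] + "-" * k + s[off:]
                padded.append(s)
            seqs = padded
        if len({len(s) for s in seqs}) > 1:
            aln = align_small_set(list(zip(names, seqs)))
            seqs = [aln.row(n) for n in names]
        if gene in tails:
            drop = tails[gene]
            seqs = [s[: len(s) - drop] for s in seqs]
        for name, s in zip(names, seqs):
            parts[name].append(s)
        width = len(seqs[0])
        provenance[gene] = (col, col + width)
        col += width
    rows = ["".join(parts[n]) for n in names]
    return MultipleAlignment(names=names, rows=rows), provenance
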