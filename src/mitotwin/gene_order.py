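"""Mitochondrial gene orders as signed circular permutations.

Orders are canonicalized by rotating to a fixed anchor (tRNA-Phe) and, when
the anchor lies on the reverse strand, flipping the whole circle, so two
annotations of the same molecule written from different origins or strands
compare equal.  Rearrangement between two orders is summarized as moved
genes, duplications, extra non-coding blocks, and the breakpoint count on
the shared single-copy gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import GeneAnnotation, MitoGenome, ValidationError

DEFAULT_ANCHOR = "trnF"


@dataclass(frozen=True)
class OrderedGene:
    name: str
    strand: str  # heavy | light
    copy_index: int = 1
    kind: str = "other"
    pseudo: bool = False

    @property
    def signed(self) -> tuple[str, int]:
        return (self.name, 1 if self.strand == "heavy" else -1)


@dataclass
class GeneOrder:
    genes: list[OrderedGene]
    anchor: str = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        self.genes = _canonicalize(self.genes, self.anchor)

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    def single_copy(self, exclude_nc: bool = True,
                    exclude_pseudo: bool = True) -> list[OrderedGene]:
        counts: dict[str, int] = {}
        for g in self.genes:
            if exclude_pseudo and g.pseudo:
                continue
            counts[g.name] = counts.get(g.name, 0) + 1
        out = []
        for g in self.genes:
            if exclude_pseudo and g.pseudo:
                continue
            if exclude_nc and g.kind == "NC":
                continue
            if counts[g.name] == 1:
                out.append(g)
        return out

    def duplicated(self) -> list[str]:
        counts: dict[str, int] = {}
        for g in self.genes:
            counts[g.name] = counts.get(g.name, 0) + 1
        return sorted(n for n, c in counts.items() if c > 1)

    def nc_count(self) -> int:
        return sum(1 for g in self.genes if g.kind == "NC")


def _flip(genes: list[OrderedGene]) -> list[OrderedGene]:
    return [
        OrderedGene(g.name, "light" if g.strand == "heavy" else "heavy",
                    g.copy_index, g.kind, g.pseudo)
        for g in reversed(genes)
    ]


def _canonicalize(genes: list[OrderedGene], anchor: str) -> list[OrderedGene]:
    names = [g.name for g in genes]
    if anchor not in names:
        return list(genes)
    i = names.index(anchor)
    rotated = genes[i:] + genes[:i]
    if rotated[0].strand == "light":  # reflect so the anchor reads heavy
        rotated = _flip(rotated)
        i = [g.name for g in rotated].index(anchor)
        rotated = rotated[i:] + rotated[:i]
    return rotated


def extract_order(genome_or_annotations: MitoGenome | Sequence[GeneAnnotation],
                  anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Gene order around the circle from annotations (sorted by start)."""
    if isinstance(genome_or_annotations, MitoGenome):
        anns = genome_or_annotations.annotations
    else:
        anns = list(genome_or_annotations)
    if not anns:
        raise ValidationError("no annotations")
    ordered = sorted(anns, key=lambda a: a.start)
    genes = [
        OrderedGene(a.name, a.strand, a.copy_index, a.kind, a.pseudo)
        for a in ordered
    ]
    return GeneOrder(genes=genes, anchor=anchor)


@dataclass
class RearrangementReport:
    moved_genes: list[str]
    duplicated_elements: list[str]
    extra_noncoding_blocks: int
    breakpoint_count: int

    @property
    def identical(self) -> bool:
        return self.breakpoint_count == 0 and not self.moved_genes


def _norm_adj(a: tuple[str, int], b: tuple[str, int]) -> tuple:
    """Strand-aware adjacency, normalized so the two reading directions of
    the circle produce the same key."""
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def compare_orders(order_a: GeneOrder, order_b: GeneOrder
                   ) -> RearrangementReport:
    """Rearrangement summary of order A relative to order B.

    Breakpoints and moved genes are computed on the single-copy genes shared
    by both orders (duplicates, NC blocks and pseudogenes excluded);
    duplications and NC-count differences are reported separately.
    """
    sc_a = {g.name: g for g in order_a.single_copy()}
    sc_b = {g.name: g for g in order_b.single_copy()}
    shared = set(sc_a) & set(sc_b)
    if len(shared) < 4:
        raise ValidationError("fewer than 4 shared single-copy genes")
    genes_a = [g for g in order_a.single_copy() if g.name in shared]
    genes_b = [g for g in order_b.single_copy() if g.name in shared]
    adj_a = {_norm_adj(genes_a[i].signed, genes_a[(i + 1) % len(genes_a)].signed)
             for i in range(len(genes_a))}
    adj_b = {_norm_adj(genes_b[i].signed, genes_b[(i + 1) % len(genes_b)].signed)
             for i in range(len(genes_b))}
    breakpoints = len(adj_a - adj_b)

    # moved = neighbourhood changed: a gene whose (predecessor, successor)
    # pair on the shared set differs between orders, or whose strand flips
    def context(genes: list[OrderedGene]) -> dict[str, tuple]:
        n = len(genes)
        ctx = {}
        for i, g in enumerate(genes):
            prev = genes[(i - 1) % n].signed
            nxt = genes[(i + 1) % n].signed
            rev_prev = (nxt[0], -nxt[1])
            rev_nxt = (prev[0], -prev[1])
            sign = 1 if g.strand == "heavy" else -1
            ctx[g.name] = min(
                (sign, prev, nxt), (-sign, rev_prev, rev_nxt))
        return ctx

    ctx_a = context(genes_a)
    ctx_b = context(genes_b)
    moved = sorted(n for n in shared if ctx_a[n] != ctx_b[n])

    dup_a = set(order_a.duplicated())
    dup_b = set(order_b.duplicated())
    duplicated = sorted(dup_a ^ dup_b)
    extra_nc = order_a.nc_count() - order_b.nc_count()
    return RearrangementReport(
        moved_genes=moved, duplicated_elements=duplicated,
        extra_noncoding_blocks=extra_nc, breakpoint_count=breakpoints,
    )


# ---------------------------------------------------------------------------
# reference orders
#
# The standard vertebrate heavy-strand order, and the rearranged order
# discovered in the Tuatara: after ND4 the section runs ND6, trnE, NC1,
# trnL2 (first copy), ND5, trnT, trnH, NC2, trnL2 (second copy), Cytb,
# trnP, trnS1, NC3, with duplicated trnK (a putative pseudogene) and
# trnL2, and three non-coding Control-Region blocks.

def _mk(spec: list[tuple]) -> list[OrderedGene]:
    out = []
    for item in spec:
        name, strand, kind = item[0], item[1], item[2]
        copy_index = item[3] if len(item) > 3 else 1
        pseudo = len(item) > 4 and item[4]
        out.append(OrderedGene(name, strand, copy_index, kind, pseudo))
    return out


STANDARD_VERTEBRATE = GeneOrder(genes=_mk([
    ("trnF", "heavy", "tRNA"),
    ("rrnS", "heavy", "rRNA"),
    ("trnV", "heavy", "tRNA"),
    ("rrnL", "heavy", "rRNA"),
    ("trnL1", "heavy", "tRNA"),
    ("ND1", "heavy", "CDS"),
    ("trnI", "heavy", "tRNA"),
    ("trnQ", "light", "tRNA"),
    ("trnM", "heavy", "tRNA"),
    ("ND2", "heavy", "CDS"),
    ("trnW", "heavy", "tRNA"),
    ("trnA", "light", "tRNA"),
    ("trnN", "light", "tRNA"),
    ("trnC", "light", "tRNA"),
    ("trnY", "light", "tRNA"),
    ("COI", "heavy", "CDS"),
    ("trnS2", "light", "tRNA"),
    ("trnD", "heavy", "tRNA"),
    ("COII", "heavy", "CDS"),
    ("trnK", "heavy", "tRNA"),
    ("ATP8", "heavy", "CDS"),
    ("ATP6", "heavy", "CDS"),
    ("COIII", "heavy", "CDS"),
    ("trnG", "heavy", "tRNA"),
    ("ND3", "heavy", "CDS"),
    ("trnR", "heavy", "tRNA"),
    ("ND4L", "heavy", "CDS"),
    ("ND4", "heavy", "CDS"),
    ("trnH", "heavy", "tRNA"),
    ("trnS1", "heavy", "tRNA"),
    ("trnL2", "heavy", "tRNA"),
    ("ND5", "heavy", "CDS"),
    ("ND6", "light", "CDS"),
    ("trnE", "light", "tRNA"),
    ("Cytb", "heavy", "CDS"),
    ("trnT", "heavy", "tRNA"),
    ("trnP", "light", "tRNA"),
    ("CR", "heavy", "NC"),
]))

TUATARA = GeneOrder(genes=_mk([
    ("trnF", "heavy", "tRNA"),
    ("rrnS", "heavy", "rRNA"),
    ("trnV", "heavy", "tRNA"),
    ("rrnL", "heavy", "rRNA"),
    ("trnL1", "heavy", "tRNA"),
    ("ND1", "heavy", "CDS"),
    ("trnI", "heavy", "tRNA"),
    ("trnQ", "light", "tRNA"),
    ("trnM", "heavy", "tRNA"),
    ("ND2", "heavy", "CDS"),
    ("trnW", "heavy", "tRNA"),
    ("trnA", "light", "tRNA"),
    ("trnN", "light", "tRNA"),
    ("trnC", "light", "tRNA"),
    ("trnY", "light", "tRNA"),
    ("COI", "heavy", "CDS"),
    ("trnS2", "light", "tRNA"),
    ("trnD", "heavy", "tRNA"),
    ("COII", "heavy", "CDS"),
    ("trnK", "heavy", "tRNA", 1),
    ("trnK", "heavy", "tRNA", 2, True),  # duplicated, putative pseudogene
    ("ATP8", "heavy", "CDS"),
    ("ATP6", "heavy", "CDS"),
    ("COIII", "heavy", "CDS"),
    ("trnG", "heavy", "tRNA"),
    ("ND3", "heavy", "CDS"),
    ("trnR", "heavy", "tRNA"),
    ("ND4L", "heavy", "CDS"),
    ("ND4", "heavy", "CDS"),
    ("ND6", "light", "CDS"),
    ("trnE", "light", "tRNA"),
    ("NC1", "heavy", "NC"),
    ("trnL2", "heavy", "tRNA", 1),
    ("ND5", "heavy", "CDS"),
    ("trnT", "heavy", "tRNA"),
    ("trnH", "heavy", "tRNA"),
    ("NC2", "heavy", "NC"),
    ("trnL2", "heavy", "tRNA", 2),
    ("Cytb", "heavy", "CDS"),
    ("trnP", "light", "tRNA"),
    ("trnS1", "heavy", "tRNA"),
    ("NC3", "heavy", "NC"),
]))
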