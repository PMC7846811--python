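"""Molecular sanity checks for candidate mitochondrial genomes.

A real vertebrate mt-molecule shows a strand bias against guanine, its 13
protein-coding genes translate under the vertebrate mitochondrial code with
no internal stop codons, its tRNA genes fold into cloverleafs (allowing the
D-arm replacement loop seen in some mt-tRNAs), and the region between
tRNA-Asn and tRNA-Cys can host a light-strand replication-origin stem-loop.
These checks separate genuine mt-molecules from nuclear copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import GeneAnnotation, MitoGenome, ValidationError, reverse_complement

# vertebrate mitochondrial code (NCBI translation table 2)
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})
_CODE = {}


def _build_code() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[2]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def mito_translate(seq: str) -> str:
    global _CODE
    if not _CODE:
        _CODE = _build_code()
    return "".join(
        _CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# composition


@dataclass
class CompositionReport:
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def guanine_pct_heavy(self) -> float:
        return self.percentages["G"]


def base_composition(genome: MitoGenome | str) -> CompositionReport:
    """Base counts and percentages on the heavy strand (the FASTA strand).

    N bases are excluded from the denominator.
    """
    seq = genome.sequence if isinstance(genome, MitoGenome) else genome
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * c / total for b, c in counts.items()}
    return CompositionReport(counts=counts, percentages=pct)


# ---------------------------------------------------------------------------
# translation


@dataclass
class CDSTranslation:
    gene: str
    protein: str
    start_codon: str
    stop_codon: str  # the terminal codon, possibly "T"/"TA" (incomplete)
    stop_complete: bool
    internal_stop_positions: list[int]  # codon indices (0-based)
    frame_ok: bool


@dataclass
class TranslationReport:
    per_cds: list[CDSTranslation]

    @property
    def passed(self) -> bool:
        return all(not c.internal_stop_positions for c in self.per_cds)


def translate_cds(genome: MitoGenome,
                  annotations: Optional[Iterable[GeneAnnotation]] = None
                  ) -> TranslationReport:
    """Translate every CDS under the vertebrate mitochondrial code.

    Light-strand genes are reverse-complemented first.  Incomplete terminal
    stops (a trailing T or TA, completed by polyadenylation in vivo) are
    accepted and flagged rather than failed; a residual frame problem is
    reported per gene, not fatal.
    """
    anns = list(annotations) if annotations is not None else [
        a for a in genome.annotations if a.kind == "CDS"
    ]
    out = []
    for ann in anns:
        if ann.kind != "CDS":
            continue
        orf = genome.feature_sequence(ann)  # already reading orientation
        remainder = len(orf) % 3
        stop_complete = True
        stop_codon = orf[-3:]
        frame_ok = True
        body = orf
        if remainder and orf[-remainder:] in ("T", "TA"):
            stop_codon = orf[-remainder:]
            stop_complete = False
            body = orf[:-remainder]
        elif remainder:
            frame_ok = False
            body = orf[: len(orf) - remainder]
        protein = mito_translate(body)
        internal = [i for i, aa in enumerate(protein[:-1]) if aa == "*"]
        if stop_complete and protein.endswith("*"):
            protein = protein[:-1]
        out.append(CDSTranslation(
            gene=ann.name, protein=protein, start_codon=orf[:3],
            stop_codon=stop_codon, stop_complete=stop_complete,
            internal_stop_positions=internal, frame_ok=frame_ok,
        ))
    return TranslationReport(per_cds=out)


# ---------------------------------------------------------------------------
# tRNA cloverleaf folding (constrained combinatorial search)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _stem_defects(five: str, three: str) -> Optional[int]:
    """Non-Watson-Crick count pairing 5' arm against reversed 3' arm.

    Returns None when more than one position is neither WC nor G.T wobble.
    """
    defects = 0
    for a, b in zip(five, reversed(three)):
        if (a, b) in _WC:
            continue
        defects += 1
        if defects > 1:
            return None
    return defects


@dataclass
class TRNAStructure:
    folded: bool
    acceptor_len: int = 0
    d_stem_len: int = 0
    d_arm_replacement_loop: bool = False
    anticodon: str = ""
    arms: dict[str, bool] = field(default_factory=dict)
    pairing: list[tuple[int, int]] = field(default_factory=list)
    score: float = 0.0


def fold_trna(sequence: str) -> TRNAStructure:
    """Search for the best cloverleaf consistent with tRNA arm constraints.

    Acceptor stem 6-8 bp, D arm 3-4 bp stem with 4-12 nt loop or a D-arm
    replacement loop, anticodon stem 5 bp with a 7 nt loop, T arm 4-5 bp stem
    with 5-9 nt loop; one G.U or mismatch allowed per stem.  Returns the
    best-scoring structure, or a not-folded result when no arrangement
    satisfies the constraints.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if not (55 <= n <= 95):
        raise ValidationError("tRNA candidate must be 55-95 nt")

    best: Optional[TRNAStructure] = None
    for disc in (1, 0, 2):
        for a_len in (7, 8, 6):
            if 2 * a_len + disc >= n:
                continue
            acc_def = _stem_defects(seq[:a_len], seq[n - disc - a_len : n - disc])
            if acc_def is None:
                continue
            inner_end = n - disc - a_len
            for sp1 in (2, 1, 3):
                d_options: list[tuple[int, int, Optional[int]]] = []
                for d_len in (4, 3):
                    for d_loop in range(4, 13):
                        d_options.append((d_len, d_loop, None))
                for repl in range(4, 13):
                    d_options.append((0, repl, 0))
                for d_len, d_loop, _ in d_options:
                    i = a_len + sp1
                    d_end = i + (2 * d_len + d_loop if d_len else d_loop)
                    if d_len:
                        d_def = _stem_defects(seq[i : i + d_len],
                                              seq[i + d_len + d_loop : d_end])
                        if d_def is None:
                            continue
                    else:
                        d_def = 0
                    for sp2 in (1, 0, 2):
                        ac = d_end + sp2
                        ac_end = ac + 17  # 5 + 7 + 5
                        if ac_end >= inner_end:
                            continue
                        ac_def = _stem_defects(seq[ac : ac + 5],
                                               seq[ac + 12 : ac_end])
                        if ac_def is None:
                            continue
                        for t_len in (5, 4):
                            for t_loop in range(5, 10):
                                t_start = inner_end - (2 * t_len + t_loop)
                                var = t_start - ac_end
                                if not (3 <= var <= 23):
                                    continue
                                t_def = _stem_defects(
                                    seq[t_start : t_start + t_len],
                                    seq[t_start + t_len + t_loop : inner_end])
                                if t_def is None:
                                    continue
                                score = (
                                    30.0
                                    + (10.0 if d_len else 4.0)
                                    - 2.0 * (acc_def + d_def + ac_def + t_def)
                                    - abs(a_len - 7)
                                    - 0.1 * abs(var - 4)
                                )
                                if best is not None and score <= best.score:
                                    continue
                                anticodon = seq[ac + 7 : ac + 10]
                                best = TRNAStructure(
                                    folded=True, acceptor_len=a_len,
                                    d_stem_len=d_len,
                                    d_arm_replacement_loop=(d_len == 0),
                                    anticodon=anticodon,
                                    arms={"acceptor": True, "D": d_len > 0,
                                          "anticodon": True, "T": True},
                                    score=score,
                                )
    return best if best is not None else TRNAStructure(folded=False)


# ---------------------------------------------------------------------------
# O_L-like stem-loop scan


@dataclass
class StemLoop:
    position: int  # window-local start of the hairpin
    genome_position: int
    stem_length: int
    loop_length: int
    overlap_upstream_trna: int = 0
    overlap_downstream_trna: int = 0
    elongation_motif_present: bool = False
    mismatches: int = 0


def _pairs(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


def find_hairpins(seq: str, min_stem: int = 5,
                  loop_range: tuple[int, int] = (3, 20),
                  max_mismatch: int = 0) -> list[tuple[int, int, int, int]]:
    """All maximal hairpins (start, stem, loop, mismatches) in a sequence.

    Stems extend outward from each candidate loop while bases pair (WC or
    G.T), tolerating ``max_mismatch`` internal mismatches; nested hits are
    suppressed in favour of the containing one.
    """
    hits = []
    n = len(seq)
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for loop_start in range(1, n - loop_len):
            i = loop_start - 1
            j = loop_start + loop_len
            stem = 0
            mism = 0
            while i >= 0 and j < n:
                if _pairs(seq[i], seq[j]):
                    pass
                elif mism < max_mismatch and stem > 0:
                    mism += 1
                else:
                    break
                stem += 1
                i -= 1
                j += 1
            # trim so the outermost position is a true pair, then recount
            while stem and not _pairs(seq[loop_start - stem],
                                      seq[loop_start + loop_len + stem - 1]):
                stem -= 1
            if stem:
                mism = sum(
                    not _pairs(seq[loop_start - 1 - t],
                               seq[loop_start + loop_len + t])
                    for t in range(stem)
                )
            if stem >= min_stem:
                hits.append((loop_start - stem, stem, loop_len, mism))
    # containment filter: keep hairpins not contained in a longer-stem one
    hits.sort(key=lambda h: (-h[1], h[3], h[0]))
    kept: list[tuple[int, int, int, int]] = []
    for h in hits:
        h_iv = (h[0], h[0] + 2 * h[1] + h[2])
        contained = any(
            k[0] <= h_iv[0] and h_iv[1] <= k[0] + 2 * k[1] + k[2]
            for k in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: h[0])
    return kept


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def scan_ol_stemloop(genome: MitoGenome,
                     window: Optional[tuple[int, int]] = None,
                     upstream_trna: str = "trnN",
                     downstream_trna: str = "trnC",
                     min_stem: int = 5) -> list[StemLoop]:
    """Scan for light-strand replication-origin-like hairpins.

    The default window is the region between tRNA-Asn and tRNA-Cys extended
    into both tRNAs, so structures overlapping the flanking tRNAs (as seen
    in unusual O_L arrangements) are found and their overlaps reported.  The
    elongation motif is a 5'-GGC-3' heavy-strand triplet at the stem base
    (the template of the 3'-CGG-5' light-strand elongation signal).
    """
    up = down = None
    try:
        up = genome.get_annotation(upstream_trna)
        down = genome.get_annotation(downstream_trna)
    except KeyError:
        pass
    if window is None:
        if up is None or down is None:
            return []
        window = (up.start, down.end)
    w_start, w_end = window
    seq = genome.sequence[w_start:w_end]
    out = []
    for start, stem, loop, mism in find_hairpins(seq, min_stem=min_stem):
        g_start = w_start + start
        g_end = g_start + 2 * stem + loop
        base_region = genome.sequence[max(0, g_end - stem - 2) : g_end + 2]
        out.append(StemLoop(
            position=start, genome_position=g_start, stem_length=stem,
            loop_length=loop,
            overlap_upstream_trna=_overlap((g_start, g_end),
                                           (up.start, up.end)) if up else 0,
            overlap_downstream_trna=_overlap((g_start, g_end),
                                             (down.start, down.end)) if down else 0,
            elongation_motif_present="GGC" in base_region,
            mismatches=mism,
        ))
    return out


# ---------------------------------------------------------------------------
# site-class summary (site classifications supplied externally)


@dataclass
class SiteClassSummary:
    n_flagged: int
    per_class_flagged: dict[str, int]
    per_class_pct_of_flagged: dict[str, int]  # integer percent


def site_class_fraction(site_table: Sequence[tuple[object, str, bool]]
                        ) -> SiteClassSummary:
    """Share of flagged sites falling in each structural class.

    ``site_table`` rows are (site, class, flagged) with class one of
    transmembrane / loop / other; only the summary fractions are computed
    here — the site-level selection and structure analyses are inputs.
    """
    rows = list(site_table)
    if not rows:
        raise ValidationError("empty site table")
    classes = sorted({c for _, c, _ in rows})
    flagged = [(s, c) for s, c, f in rows if f]
    n_flagged = len(flagged)
    per_class = {c: sum(1 for _, cc in flagged if cc == c) for c in classes}
    pct = {
        c: (round(100.0 * per_class[c] / n_flagged) if n_flagged else 0)
        for c in classes
    }
    return SiteClassSummary(n_flagged=n_flagged, per_class_flagged=per_class,
                            per_class_pct_of_flagged=pct)
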