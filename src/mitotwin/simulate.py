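"""Synthetic two-molecule mitochondrial data with known truth labels.

Emulates an individual carrying two deeply divergent circular mt-genomes:
an ancestor with the standard vertebrate gene order is evolved into two
molecules (M1, M2) under a Kimura two-parameter substitution process with
coding constraints, the non-coding (putative Control Region) blocks are
homogenized within each genome to mimic concerted evolution, and short
paired-end plus long indel-rich read mixtures are drawn with per-read
origin labels retained.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .io import (
    GeneAnnotation,
    MitoGenome,
    Read,
    ReadSet,
    ValidationError,
    reverse_complement,
)

# vertebrate mitochondrial code (NCBI table 2): stops TAA TAG AGA AGG
MITO_STOPS = frozenset({"TAA", "TAG", "AGA", "AGG"})
BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# per-operation offsets for independent, reproducible RNG streams
_STREAM = {"ancestor": 11, "evolve": 23, "short": 37, "long": 53, "mix": 71}


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions being emulated."""

    seed: int = 0
    genome_length: int = 18078
    target_divergence: float = 0.104
    kappa: float = 4.0
    nc_block_count: int = 3
    nc_within_identity: float = 0.99
    minor_fraction: float = 0.145
    short_read_length: int = 100
    insert_mean: float = 180.0
    short_error: float = 0.001
    long_length_mean: float = 2504.5
    long_length_sd: float = 2409.2
    long_length_min: int = 514
    long_length_max: int = 16978
    long_error_sub: float = 0.03
    long_error_ins: float = 0.025
    long_error_del: float = 0.025
    depth_major: float = 17.0
    full_molecule_prob: float = 0.01

    def __post_init__(self) -> None:
        rates = [
            self.target_divergence, self.short_error, self.long_error_sub,
            self.long_error_ins, self.long_error_del, self.full_molecule_prob,
        ]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValidationError("rates must lie in [0, 1]")
        if not (0.0 < self.minor_fraction < 1.0):
            raise ValidationError("minor_fraction must lie in (0, 1)")
        if min(self.genome_length, self.short_read_length,
               self.long_length_min, self.long_length_max) <= 0:
            raise ValidationError("lengths must be positive")
        if not (0.0 <= self.nc_within_identity <= 1.0):
            raise ValidationError("nc_within_identity must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _STREAM[stream]])


@dataclass
class TruthSet:
    ancestor: MitoGenome
    genome_m1: MitoGenome
    genome_m2: MitoGenome
    realized_divergence: float
    origins: dict[str, str] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "realized_divergence": self.realized_divergence,
            "origins": self.origins,
        }


# ---------------------------------------------------------------------------
# gene model: the standard vertebrate mt order with nominal lengths

# (name, kind, strand, nominal length); CDS lengths are multiples of 3
# including start and stop codons.  tRNA lengths are set by the cloverleaf
# template (72 nt).  NC blocks absorb the remaining length.
STANDARD_VERTEBRATE_ORDER: list[tuple[str, str, str, int]] = [
    ("trnF", "tRNA", "heavy", 72),
    ("rrnS", "rRNA", "heavy", 950),
    ("trnV", "tRNA", "heavy", 72),
    ("rrnL", "rRNA", "heavy", 1600),
    ("trnL1", "tRNA", "heavy", 72),   # Leu(UUR)
    ("ND1", "CDS", "heavy", 957),
    ("trnI", "tRNA", "heavy", 72),
    ("trnQ", "tRNA", "light", 72),
    ("trnM", "tRNA", "heavy", 72),
    ("ND2", "CDS", "heavy", 1041),
    ("trnW", "tRNA", "heavy", 72),
    ("trnA", "tRNA", "light", 72),
    ("trnN", "tRNA", "light", 72),
    ("trnC", "tRNA", "light", 72),
    ("trnY", "tRNA", "light", 72),
    ("COI", "CDS", "heavy", 1551),
    ("trnS2", "tRNA", "light", 72),   # Ser(UCN)
    ("trnD", "tRNA", "heavy", 72),
    ("COII", "CDS", "heavy", 690),
    ("trnK", "tRNA", "heavy", 72),
    ("ATP8", "CDS", "heavy", 165),
    ("ATP6", "CDS", "heavy", 681),
    ("COIII", "CDS", "heavy", 786),
    ("trnG", "tRNA", "heavy", 72),
    ("ND3", "CDS", "heavy", 348),
    ("trnR", "tRNA", "heavy", 72),
    ("ND4L", "CDS", "heavy", 297),
    ("ND4", "CDS", "heavy", 1380),
    ("trnH", "tRNA", "heavy", 72),
    ("trnS1", "tRNA", "heavy", 72),   # Ser(AGY)
    ("trnL2", "tRNA", "heavy", 72),   # Leu(CUN)
    ("ND5", "CDS", "heavy", 1821),
    ("ND6", "CDS", "light", 522),
    ("trnE", "tRNA", "light", 72),
    ("Cytb", "CDS", "heavy", 1140),
    ("trnT", "tRNA", "heavy", 72),
    ("trnP", "tRNA", "light", 72),
]

# standard anticodons (DNA alphabet) for the 22 mt-tRNAs
ANTICODONS = {
    "trnF": "GAA", "trnV": "TAC", "trnL1": "TAA", "trnI": "GAT",
    "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnA": "TGC",
    "trnN": "GTT", "trnC": "GCA", "trnY": "GTA", "trnS2": "TGA",
    "trnD": "GTC", "trnK": "TTT", "trnG": "TCC", "trnR": "TCG",
    "trnH": "GTG", "trnS1": "GCT", "trnL2": "TAG", "trnE": "TTC",
    "trnT": "TGT", "trnP": "TGG",
}

_GENE_TOTAL = sum(length for _, _, _, length in STANDARD_VERTEBRATE_ORDER)
_MIN_NC = 200

# heavy-strand base frequencies (A, C, G, T): vertebrate mtDNA is strongly
# G-poor on the heavy strand, the bias the QC composition check looks for
HEAVY_FREQS = np.array([0.33, 0.28, 0.14, 0.25])

# fixed cloverleaf template layout (see make_trna_sequence): offsets of the
# paired stem positions within a 72-nt tRNA, used to keep stems intact when
# the genomes diverge
_TRNA_STEM_PAIRS: list[tuple[int, int]] = (
    [(i, 70 - i) for i in range(7)]            # acceptor
    + [(9 + j, 24 - j) for j in range(4)]      # D
    + [(26 + j, 42 - j) for j in range(5)]     # anticodon
    + [(47 + j, 63 - j) for j in range(5)]     # T
)
_TRNA_STEM_OFFSETS = frozenset(p for pair in _TRNA_STEM_PAIRS for p in pair)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random sense codons (no vertebrate-mito stop codons)."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(BASES), size=3, p=HEAVY_FREQS))
        if codon not in MITO_STOPS:
            out.append(codon)
    return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(BASES))[
        rng.choice(4, size=n, p=HEAVY_FREQS)])


def make_trna_sequence(rng: np.random.Generator, anticodon: str) -> str:
    """A 72-nt cloverleaf with perfect Watson-Crick stems.

    Layout: acceptor 7 bp, D arm 4 bp stem + 8 nt loop, anticodon arm 5 bp
    stem + 7 nt loop (anticodon at loop centre), 4 nt variable region,
    T arm 5 bp stem + 7 nt loop, 1 nt discriminator.
    """
    def stem(n):
        s = _random_seq(rng, n)
        return s, reverse_complement(s)

    acc5, acc3 = stem(7)
    d5, d3 = stem(4)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    d_loop = _random_seq(rng, 8)
    ac_loop = _random_seq(rng, 2) + anticodon + _random_seq(rng, 2)
    t_loop = _random_seq(rng, 7)
    var = _random_seq(rng, 4)
    disc = _random_seq(rng, 1)
    return (acc5 + "TA" + d5 + d_loop + d3 + "A" + ac5 + ac_loop + ac3
            + var + t5 + t_loop + t3 + acc3 + disc)


def generate_ancestor(config: SimConfig) -> MitoGenome:
    """Build a circular ancestor genome in the standard vertebrate gene order.

    CDS features are valid vertebrate-mito ORFs (ATG start, terminal TAA, no
    internal stops); tRNAs come from cloverleaf templates; the remaining
    length is split across ``nc_block_count`` non-coding blocks appended as
    NC1..NCk after the last gene (the Control-Region position).
    """
    if config.genome_length < 16000:
        raise ValidationError("genome_length too small to host the gene model")
    rng = config.rng("ancestor")
    nc_total = config.genome_length - _GENE_TOTAL
    if nc_total < _MIN_NC * config.nc_block_count:
        raise ValidationError("genome_length too small for the NC blocks")
    nc_len = nc_total // config.nc_block_count
    nc_lens = [nc_len] * config.nc_block_count
    nc_lens[-1] += nc_total - nc_len * config.nc_block_count

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0
    for name, kind, strand, length in STANDARD_VERTEBRATE_ORDER:
        if kind == "CDS":
            n_codons = length // 3
            orf = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
            seq = reverse_complement(orf) if strand == "light" else orf
        elif kind == "tRNA":
            body = make_trna_sequence(rng, ANTICODONS[name])
            seq = reverse_complement(body) if strand == "light" else body
            length = len(seq)
        else:  # rRNA
            seq = _random_seq(rng, length)
        annotations.append(GeneAnnotation(name, kind, pos, pos + length, strand))
        parts.append(seq)
        pos += length
    # NC blocks: one master sequence copied to every block (pre-homogenized)
    master = _random_seq(rng, nc_lens[0])
    for i, length in enumerate(nc_lens, 1):
        seq = (master + _random_seq(rng, length - len(master)))[:length]
        annotations.append(
            GeneAnnotation(f"NC{i}", "NC", pos, pos + length, "heavy", copy_index=1)
        )
        parts.append(seq)
        pos += length
    return MitoGenome(
        id="ancestor", sequence="".join(parts), circular=True,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# divergence


def _codon_context(genome: MitoGenome) -> dict[int, tuple[int, int, str, int]]:
    """Map genome position -> (cds_start, cds_end, strand, offset in ORF).

    Offset is the 0-based position within the reading-orientation ORF.
    """
    ctx = {}
    for ann in genome.annotations:
        if ann.kind != "CDS":
            continue
        n = ann.length
        for i in range(n):
            p = (ann.start + i) % len(genome)
            off = i if ann.strand == "heavy" else n - 1 - i
            ctx[p] = (ann.start, ann.end, ann.strand, off)
    return ctx


def _mutate_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    """K2P single-base substitution: transition w.p. kappa/(kappa+2)."""
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tvs = [b for b in BASES if b != base and b != _TRANSITION[base]]
    return tvs[rng.integers(0, 2)]


def _apply_mutations(genome: MitoGenome, positions: np.ndarray,
                     rng: np.random.Generator, kappa: float) -> str:
    """Substitute at the given positions, never creating an internal stop,
    never touching a start or terminal stop codon."""
    seq = list(genome.sequence)
    ctx = _codon_context(genome)
    for p in positions:
        p = int(p)
        info = ctx.get(p)
        if info is None:
            seq[p] = _mutate_base(rng, seq[p], kappa)
            continue
        start, end, strand, off = info
        n = end - start
        if off < 3 or off >= n - 3:  # protect start and stop codons
            continue
        codon_idx = off // 3
        # genome positions of this codon in reading order
        if strand == "heavy":
            cpos = [start + 3 * codon_idx + j for j in range(3)]
        else:
            cpos = [start + (n - 1 - (3 * codon_idx + j)) for j in range(3)]
        for _ in range(8):  # rejection sampling against internal stops
            new = _mutate_base(rng, seq[p], kappa)
            codon = ""
            for q in cpos:
                b = new if q == p else seq[q % len(seq)]
                if strand == "light":
                    b = reverse_complement(b)
                codon += b
            if codon not in MITO_STOPS:
                seq[p] = new
                break
    return "".join(seq)


def _protected_positions(genome: MitoGenome) -> np.ndarray:
    """Positions never mutated: CDS start/stop codons and tRNA stem pairs.

    Real mt-tRNA stems evolve under compensatory pairing; holding them fixed
    keeps every simulated genome foldable without modelling covariation.
    """
    protected: set[int] = set()
    for ann in genome.annotations:
        if ann.kind == "CDS":
            n = ann.length
            for i in list(range(3)) + list(range(n - 3, n)):
                protected.add((ann.start + i) % len(genome))
        elif ann.kind == "tRNA":
            n = ann.length
            for off in _TRNA_STEM_OFFSETS:
                if off >= n:
                    continue
                i = off if ann.strand == "heavy" else n - 1 - off
                protected.add((ann.start + i) % len(genome))
    return np.fromiter(protected, dtype=np.int64)


def _nc_blocks(genome: MitoGenome) -> list[GeneAnnotation]:
    return sorted((a for a in genome.annotations if a.kind == "NC"),
                  key=lambda a: a.start)


def _homogenize_nc(seq: str, genome: MitoGenome, noise_rate: float,
                   kappa: float, base_seed: int) -> str:
    """Copy the first NC block over the others with small independent noise.

    The noise RNG is seeded from the master sequence content, so identical
    masters in the two genomes produce identical copies (a zero-divergence
    pair stays identical).
    """
    blocks = _nc_blocks(genome)
    if len(blocks) < 2:
        return seq
    s = list(seq)
    master = seq[blocks[0].start : blocks[0].end]
    key = zlib.crc32(master.encode()) % (2**31)
    rng = np.random.default_rng([base_seed % (2**31), key])
    for blk in blocks[1:]:
        copy = list(master[: blk.length])
        n_noise = rng.binomial(len(copy), noise_rate)
        for p in rng.choice(len(copy), size=min(n_noise, len(copy)), replace=False):
            copy[p] = _mutate_base(rng, copy[p], kappa)
        tail = seq[blk.start + len(copy) : blk.end]
        s[blk.start : blk.end] = copy + list(tail)
    return "".join(s)


def p_distance_strings(a: str, b: str) -> float:
    """Raw proportion of differing sites between equal-length ungapped strings."""
    if len(a) != len(b):
        raise ValidationError("sequences must be equal length")
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    valid = (arr_a != ord("N")) & (arr_b != ord("N"))
    if valid.sum() == 0:
        raise ValidationError("no comparable sites")
    return float(((arr_a != arr_b) & valid).sum() / valid.sum())


def evolve_pair(ancestor: MitoGenome, config: SimConfig
                ) -> tuple[MitoGenome, MitoGenome, float]:
    """Evolve two descendant molecules to the target pairwise divergence.

    Each lineage receives half the target divergence at disjoint random
    positions under a K2P substitution process; coding constraints are
    enforced by per-codon rejection; NC blocks are then homogenized within
    each genome (concerted-evolution signature).
    """
    rng = config.rng("evolve")
    L = len(ancestor)
    n_total = int(round(config.target_divergence * L))
    allowed = np.setdiff1d(np.arange(L), _protected_positions(ancestor))
    if n_total > len(allowed):
        raise ValidationError("target divergence exceeds mutable positions")
    positions = rng.choice(allowed, size=n_total, replace=False)
    pos1, pos2 = positions[::2], positions[1::2]

    seq1 = _apply_mutations(ancestor, pos1, rng, config.kappa)
    seq2 = _apply_mutations(
        MitoGenome("tmp", ancestor.sequence, True, list(ancestor.annotations)),
        pos2, rng, config.kappa)

    # the noise stream is keyed on the master-block content (same base
    # seed for both genomes): identical masters copy identically, so a
    # zero-divergence pair stays bit-identical
    noise = 1.0 - config.nc_within_identity
    seq1 = _homogenize_nc(seq1, ancestor, noise, config.kappa, config.seed + 101)
    seq2 = _homogenize_nc(seq2, ancestor, noise, config.kappa, config.seed + 101)

    m1 = MitoGenome("M1", seq1, True, list(ancestor.annotations), molecule_tag="M1")
    m2 = MitoGenome("M2", seq2, True, list(ancestor.annotations), molecule_tag="M2")
    realized = p_distance_strings(seq1, seq2)
    if abs(realized - config.target_divergence) > 0.005:
        raise ValidationError(
            f"realized divergence {realized:.4f} misses target "
            f"{config.target_divergence:.4f} by more than 0.005"
        )
    return m1, m2, realized


# ---------------------------------------------------------------------------
# reads


def _add_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for p in rng.choice(len(arr), size=min(n_err, len(arr)), replace=False):
        arr[p] = BASES[(BASES.index(arr[p]) + 1 + rng.integers(0, 3)) % 4]
    return "".join(arr)


def _add_indel_errors(rng: np.random.Generator, seq: str,
                      sub: float, ins: float, del_: float) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < del_:
            continue
        if r < del_ + sub:
            ch = BASES[(BASES.index(ch) + 1 + rng.integers(0, 3)) % 4]
        out.append(ch)
        if rng.random() < ins:
            out.append(BASES[rng.integers(0, 4)])
    return "".join(out)


def simulate_short_reads(genome: MitoGenome, config: SimConfig,
                         depth: Optional[float] = None,
                         prefix: str = "sr") -> ReadSet:
    """Paired-end reads from uniformly placed fragments on the circle.

    Insert sizes are Normal(insert_mean, 0.1*insert_mean); fragments may wrap
    the origin; substitution errors at ``short_error``; mate 2 is the reverse
    complement of the fragment end.
    """
    rng = config.rng("short")
    depth = config.depth_major if depth is None else depth
    L = len(genome)
    rl = config.short_read_length
    n_pairs = int(round(depth * L / (2 * rl)))
    doubled = genome.sequence * 2
    origin = genome.molecule_tag
    reads = []
    for i in range(n_pairs):
        insert = max(rl, int(round(rng.normal(config.insert_mean,
                                              0.1 * config.insert_mean))))
        insert = min(insert, L)
        start = int(rng.integers(0, L))
        frag = doubled[start : start + insert]
        r1 = _add_substitutions(rng, frag[:rl], config.short_error)
        r2 = _add_substitutions(rng, reverse_complement(frag[-rl:]),
                                config.short_error)
        id1, id2 = f"{prefix}{i}/1", f"{prefix}{i}/2"
        reads.append(Read(id1, r1, platform="short_pe", mate_id=id2,
                          true_origin=origin))
        reads.append(Read(id2, r2, platform="short_pe", mate_id=id1,
                          true_origin=origin))
    return ReadSet(reads)


def simulate_long_reads(genome: MitoGenome, config: SimConfig,
                        n_reads: Optional[int] = None,
                        depth: Optional[float] = None,
                        prefix: str = "lr") -> ReadSet:
    """Long single-molecule reads with indel-rich errors.

    Lengths follow a lognormal moment-matched to (mean, sd), truncated to
    [min, max].  With probability ``full_molecule_prob`` a read covers the
    whole molecule on both strands (genome + reverse complement), emulating
    an end-connected native duplex read.
    """
    rng = config.rng("long")
    L = len(genome)
    if n_reads is None:
        depth = config.depth_major if depth is None else depth
        n_reads = max(1, int(round(depth * L / config.long_length_mean)))
    m, s = config.long_length_mean, config.long_length_sd
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    doubled = genome.sequence * 2
    origin = genome.molecule_tag
    reads = []
    for i in range(n_reads):
        if rng.random() < config.full_molecule_prob:
            start = int(rng.integers(0, L))
            rotated = doubled[start : start + L]
            raw = rotated + reverse_complement(rotated)
        else:
            length = int(round(np.exp(rng.normal(mu, np.sqrt(sigma2)))))
            length = int(np.clip(length, config.long_length_min,
                                 min(config.long_length_max, L)))
            start = int(rng.integers(0, L))
            raw = doubled[start : start + length]
            if rng.random() < 0.5:
                raw = reverse_complement(raw)
        seq = _add_indel_errors(rng, raw, config.long_error_sub,
                                config.long_error_ins, config.long_error_del)
        reads.append(Read(f"{prefix}{i}", seq, platform="long",
                          true_origin=origin))
    return ReadSet(reads)


def mix_reads(reads_m1: ReadSet, reads_m2: ReadSet, minor_fraction: float,
              seed: int) -> ReadSet:
    """Subsampled union where the expected M2 share equals ``minor_fraction``.

    Each output slot draws its origin Bernoulli(minor_fraction); reads are
    consumed without replacement from each pool until one is exhausted.
    """
    if not (0.0 < minor_fraction < 1.0):
        raise ValidationError("minor_fraction must lie in (0, 1)")
    if len(reads_m1) == 0 or len(reads_m2) == 0:
        raise ValidationError("both read sets must be non-empty")
    rng = np.random.default_rng([seed % (2**31), _STREAM["mix"]])
    pool1 = list(reads_m1)
    pool2 = list(reads_m2)
    rng.shuffle(pool1)
    rng.shuffle(pool2)
    n_total = int(min(len(pool1) / (1.0 - minor_fraction),
                      len(pool2) / minor_fraction))
    picks = rng.random(n_total) < minor_fraction
    out, i1, i2 = [], 0, 0
    for take_minor in picks:
        if take_minor:
            if i2 >= len(pool2):
                break
            out.append(pool2[i2]); i2 += 1
        else:
            if i1 >= len(pool1):
                break
            out.append(pool1[i1]); i1 += 1
    # drop broken mate pairings introduced by subsampling
    kept = {r.id for r in out}
    fixed = [
        r if (r.mate_id is None or r.mate_id in kept)
        else Read(r.id, r.sequence, r.quality, r.platform, None, r.true_origin)
        for r in out
    ]
    return ReadSet(fixed)


def simulate_truth_set(config: SimConfig) -> TruthSet:
    """Ancestor -> (M1, M2) convenience wrapper used by drivers and tests."""
    anc = generate_ancestor(config)
    m1, m2, realized = evolve_pair(anc, config)
    return TruthSet(ancestor=anc, genome_m1=m1, genome_m2=m2,
                    realized_divergence=realized)


def write_truth_manifest(path, truth: TruthSet, config: SimConfig) -> None:
    payload = {"config": asdict(config), **truth.manifest()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def evolve_lineage(genome: MitoGenome, divergence: float, seed: int,
                   label: str) -> MitoGenome:
    """Derive one descendant at a given extra divergence from a genome.

    Used to build small populations (e.g. northern/southern island groups)
    around the simulated molecules; coding and tRNA-stem constraints are
    the same as in ``evolve_pair``.
    """
    rng = np.random.default_rng([seed % (2**31), 131])
    L = len(genome)
    n = int(round(divergence * L))
    allowed = np.setdiff1d(np.arange(L), _protected_positions(genome))
    positions = rng.choice(allowed, size=min(n, len(allowed)), replace=False)
    seq = _apply_mutations(genome, positions, rng, kappa=4.0)
    return MitoGenome(label, seq, True, list(genome.annotations),
                      molecule_tag=genome.molecule_tag)


def rehomogenize_nc(genome: MitoGenome, nc_within_identity: float = 0.99,
                    kappa: float = 4.0, seed: int = 0) -> MitoGenome:
    """Re-apply concerted evolution to a genome's NC blocks.

    A lineage that keeps homogenizing its duplicated Control-Region blocks
    should show high within-genome block identity regardless of how far it
    has diverged from its relatives; this copies the genome's own first NC
    block over the others with the configured noise.
    """
    seq = _homogenize_nc(genome.sequence, genome, 1.0 - nc_within_identity,
                         kappa, seed + 17)
    return MitoGenome(genome.id, seq, genome.circular,
                      list(genome.annotations),
                      molecule_tag=genome.molecule_tag)
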