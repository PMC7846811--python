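"""Assign reads and contigs to one of two candidate mt-molecules.

A read is aligned to each reference (both orientations, reference doubled
for circularity) and called for the molecule with the higher gap-compressed
identity when the margin clears the divergence cutoff; quantities derived
from the assignment table — breadth/depth of coverage, the minor-molecule
mixture fraction with a Wilson interval, majority-vote consensus, k-mer
repeat flags and contaminant purging — are computed here too.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from scipy.stats import norm

from .io import MitoGenome, Read, ReadSet, ValidationError, reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

DEFAULT_DELTA = 0.05
DEFAULT_MIN_LEN = 500


@dataclass(frozen=True)
class AlignmentHit:
    identity: float
    span: tuple[int, int]  # reference interval, start modulo L, half-open
    matches: int = 0
    mismatches: int = 0
    gap_openings: int = 0
    strand: str = "+"
    cigar: str = ""
    raw_start: int = 0  # start on the doubled reference (for consensus)


EMPTY_HIT = AlignmentHit(identity=0.0, span=(0, 0))


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    matches = mismatches = gap_openings = 0
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        if op == "=":
            matches += n
        elif op == "X":
            mismatches += n
        elif op in "ID":
            gap_openings += 1  # gap-compressed: any run counts once
    return matches, mismatches, gap_openings


def align_identity(read_seq: str, reference: MitoGenome | str,
                   circular: Optional[bool] = None,
                   max_div: float = 0.35) -> AlignmentHit:
    """Best local (infix) alignment of a read against a reference.

    Both orientations are tried; a circular reference is doubled so reads
    spanning the origin align contiguously.  Identity is gap-compressed:
    matches / (matches + mismatches + gap openings), each contiguous gap
    counting once.  The span is reported on the unwrapped reference, start
    taken modulo its length.  Alignments beyond ``max_div`` edit fraction
    are not pursued and report identity 0 with an empty span.
    """
    if isinstance(reference, MitoGenome):
        ref_seq = reference.sequence
        circ = reference.circular if circular is None else circular
    else:
        ref_seq = reference
        circ = bool(circular)
    if not read_seq or not ref_seq:
        raise ValidationError("empty sequence")
    L = len(ref_seq)
    target = ref_seq * 2 if circ else ref_seq

    # stage 1: cheap distance-only screen of both orientations
    candidates = []
    k_limit = int(max_div * len(read_seq)) if 0 < max_div < 1 else -1
    for strand, query in (("+", read_seq), ("-", reverse_complement(read_seq))):
        res = edlib.align(query, target, mode="HW", task="locations", k=k_limit)
        if res["editDistance"] >= 0 and res["locations"]:
            candidates.append((res["editDistance"], strand, query,
                               res["locations"][0]))
    if not candidates:
        return EMPTY_HIT
    # stage 2: full path only for the better orientation, on its window
    _, strand, query, (start, end) = min(candidates, key=lambda c: c[0])
    window = target[start : end + 1]
    res = edlib.align(query, window, mode="NW", task="path")
    m, x, g = _cigar_stats(res["cigar"])
    denom = m + x + g
    ident = m / denom if denom else 0.0
    return AlignmentHit(
        identity=ident, span=(start % L, start % L + (end + 1 - start)),
        matches=m, mismatches=x, gap_openings=g, strand=strand,
        cigar=res["cigar"], raw_start=start,
    )


@dataclass
class AssignmentRecord:
    read_id: str
    length: int
    identity_m1: float
    identity_m2: float
    call: str  # M1 | M2 | unassigned | too_short
    hit_m1: AlignmentHit = EMPTY_HIT
    hit_m2: AlignmentHit = EMPTY_HIT
    true_origin: Optional[str] = None


@dataclass
class AssignmentTable:
    records: list[AssignmentRecord]
    delta: float = DEFAULT_DELTA
    min_len: int = DEFAULT_MIN_LEN

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def counts(self) -> Counter:
        return Counter(r.call for r in self.records)

    def called(self, molecule: str) -> list[AssignmentRecord]:
        return [r for r in self.records if r.call == molecule]

    def to_tsv(self, path) -> None:
        cols = ("read_id", "length", "identity_m1", "identity_m2", "call",
                "span_m1_start", "span_m1_end", "span_m2_start", "span_m2_end")
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                fh.write("\t".join(map(str, (
                    r.read_id, r.length,
                    f"{r.identity_m1:.4f}", f"{r.identity_m2:.4f}", r.call,
                    r.hit_m1.span[0], r.hit_m1.span[1],
                    r.hit_m2.span[0], r.hit_m2.span[1],
                ))) + "\n")


def assign_reads(reads: Iterable[Read], ref_m1: MitoGenome, ref_m2: MitoGenome,
                 delta: float = DEFAULT_DELTA, min_len: int = DEFAULT_MIN_LEN,
                 delta_rel: Optional[float] = None) -> AssignmentTable:
    """Call each read M1 or M2 by gap-compressed identity margin.

    Reads shorter than ``min_len`` are set aside as too_short.  A read is
    called for the molecule with the higher identity when the identity
    difference is at least ``delta_rel`` (default half the divergence cutoff
    ``delta``: a read from one molecule loses the full inter-molecule
    divergence against the wrong reference, while noise is symmetric);
    exact ties and sub-margin differences are left unassigned.
    """
    if delta_rel is None:
        delta_rel = 0.5 * delta
    records = []
    for read in reads:
        if len(read) < min_len:
            records.append(AssignmentRecord(
                read.id, len(read), 0.0, 0.0, "too_short",
                true_origin=read.true_origin))
            continue
        h1 = align_identity(read.sequence, ref_m1)
        h2 = align_identity(read.sequence, ref_m2)
        diff = h1.identity - h2.identity
        if diff >= delta_rel:
            call = "M1"
        elif -diff >= delta_rel:
            call = "M2"
        else:
            call = "unassigned"
        records.append(AssignmentRecord(
            read.id, len(read), h1.identity, h2.identity, call,
            hit_m1=h1, hit_m2=h2, true_origin=read.true_origin))
    return AssignmentTable(records, delta=delta, min_len=min_len)


def screen_contigs(contigs: Sequence[tuple[str, str]], ref_primary: MitoGenome,
                   ref_secondary: MitoGenome, min_div: float = 0.05
                   ) -> dict[str, list[str]]:
    """Partition contigs by divergence against the two draft molecules.

    A contig at >= ``min_div`` divergence from one molecule and < ``min_div``
    from the other belongs to the latter; anything else is ambiguous.
    """
    out: dict[str, list[str]] = {"primary": [], "secondary": [], "ambiguous": []}
    for name, seq in contigs:
        d1 = 1.0 - align_identity(seq, ref_primary).identity
        d2 = 1.0 - align_identity(seq, ref_secondary).identity
        if d1 < min_div <= d2:
            out["primary"].append(name)
        elif d2 < min_div <= d1:
            out["secondary"].append(name)
        else:
            out["ambiguous"].append(name)
    return out


@dataclass
class CoverageSummary:
    n_reads: int
    breadth_pct: float
    depth_mean: Optional[float]
    depth_sd: Optional[float]
    depth_min: Optional[int]
    depth_max: Optional[int]
    length_mean: Optional[float]
    length_sd: Optional[float]
    length_min: Optional[int]
    length_max: Optional[int]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def coverage_summary(table: AssignmentTable, reference: MitoGenome,
                     which_molecule: str) -> CoverageSummary:
    """Breadth and depth over the reference from assigned-read spans.

    Spans wrap the circular origin.  With no assigned reads, breadth is 0 and
    the depth statistics are undefined (None), not zero.
    """
    L = len(reference)
    depth = np.zeros(L, dtype=np.int64)
    lengths = []
    hit_attr = "hit_m1" if which_molecule == "M1" else "hit_m2"
    n = 0
    for rec in table:
        if rec.call != which_molecule:
            continue
        hit: AlignmentHit = getattr(rec, hit_attr)
        start, end = hit.span
        if end <= start:
            continue
        n += 1
        lengths.append(rec.length)
        span_len = min(end - start, L)
        idx = (np.arange(start, start + span_len)) % L
        np.add.at(depth, idx, 1)
    if n == 0:
        return CoverageSummary(0, 0.0, None, None, None, None,
                               None, None, None, None)
    covered = depth > 0
    lengths_arr = np.array(lengths)
    return CoverageSummary(
        n_reads=n,
        breadth_pct=float(100.0 * covered.mean()),
        depth_mean=float(depth.mean()),
        depth_sd=float(depth.std()),
        depth_min=int(depth.min()),
        depth_max=int(depth.max()),
        length_mean=float(lengths_arr.mean()),
        length_sd=float(lengths_arr.std()),
        length_min=int(lengths_arr.min()),
        length_max=int(lengths_arr.max()),
    )


@dataclass
class MixtureEstimate:
    n_m1: int
    n_m2: int
    minor_fraction: float
    ci_low: float
    ci_high: float

    @property
    def n_assignable(self) -> int:
        return self.n_m1 + self.n_m2


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ValidationError("no trials")
    z = norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def mixture_fraction(n_m1: int | AssignmentTable, n_m2: Optional[int] = None
                     ) -> MixtureEstimate:
    """Minor-molecule share of assignable reads with a 95% Wilson CI.

    Accepts either raw counts or an AssignmentTable.
    """
    if isinstance(n_m1, AssignmentTable):
        counts = n_m1.counts()
        n1, n2 = counts.get("M1", 0), counts.get("M2", 0)
    else:
        n1, n2 = int(n_m1), int(n_m2)
    n = n1 + n2
    if n == 0:
        raise ValidationError("zero assignable reads")
    minor = min(n1, n2)
    frac = minor / n
    lo, hi = wilson_interval(minor, n)
    return MixtureEstimate(n_m1=n1, n_m2=n2, minor_fraction=frac,
                           ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# consensus

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def consensus_from_assignment(table: AssignmentTable, reads: ReadSet,
                              reference: MitoGenome, which_molecule: str,
                              min_breadth: float = 99.0) -> tuple[MitoGenome, list[int]]:
    """Majority-vote consensus over reads assigned to one molecule.

    Each assigned read is re-aligned to the doubled reference and its bases
    projected onto reference positions via the alignment path; per-position
    majority wins (reference base breaks ties).  Zero-depth positions keep
    the reference base and are returned as flagged positions.
    """
    cov = coverage_summary(table, reference, which_molecule)
    if cov.breadth_pct < min_breadth:
        raise ValidationError(
            f"breadth {cov.breadth_pct:.1f}% below {min_breadth}%: "
            "more coverage needed for a consensus"
        )
    L = len(reference)
    votes = np.zeros((L, 4), dtype=np.int64)
    by_id = {r.id: r for r in reads}
    hit_attr = "hit_m1" if which_molecule == "M1" else "hit_m2"
    for rec in table:
        if rec.call != which_molecule:
            continue
        read = by_id.get(rec.read_id)
        if read is None:
            continue
        hit: AlignmentHit = getattr(rec, hit_attr)
        seq = read.sequence if hit.strand == "+" else reverse_complement(read.sequence)
        rpos, qpos = hit.raw_start, 0
        for count, op in _CIGAR_RE.findall(hit.cigar):
            k = int(count)
            if op in "=XM":
                for j in range(k):
                    b = _BASE_IDX.get(seq[qpos + j])
                    if b is not None:
                        votes[(rpos + j) % L, b] += 1
                rpos += k
                qpos += k
            elif op == "I":
                qpos += k
            elif op == "D":
                rpos += k
    consensus = list(reference.sequence)
    flagged = []
    for p in range(L):
        total = votes[p].sum()
        if total == 0:
            flagged.append(p)
            continue
        best = int(votes[p].argmax())
        ref_b = _BASE_IDX.get(reference.sequence[p], -1)
        if ref_b >= 0 and votes[p, ref_b] == votes[p, best]:
            continue  # reference base breaks ties
        consensus[p] = "ACGT"[best]
    genome = MitoGenome(
        id=f"{reference.id}_consensus", sequence="".join(consensus),
        circular=reference.circular, annotations=list(reference.annotations),
        molecule_tag=which_molecule,
    )
    return genome, flagged


# ---------------------------------------------------------------------------
# k-mer repeat scan


@dataclass
class RepeatScanResult:
    flagged_kmers: set[str]
    regions: list[tuple[int, int]]  # merged intervals on the draft genome
    modal_count: int
    n_too_short: int


def kmer_repeat_scan(reads: Iterable[Read] | Iterable[str], draft: MitoGenome,
                     k: int = 71, expected_depth: Optional[float] = None,
                     fold: float = 1.6) -> RepeatScanResult:
    """Flag k-mers over-represented relative to the single-copy depth.

    Counts k-mers in the reads (canonical over both strands), takes the modal
    count of draft-genome k-mers as the single-copy depth unless
    ``expected_depth`` is given, flags k-mers counted at >= fold * depth, and
    localizes flagged k-mers on the draft (merged intervals).
    """
    if k % 2 == 0 or not (15 <= k <= 101):
        raise ValidationError("k must be odd and in [15, 101]")
    counts: Counter = Counter()
    n_too_short = 0
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else read
        if len(seq) < k:
            n_too_short += 1
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[min(kmer, reverse_complement(kmer))] += 1
    doubled = draft.sequence + draft.sequence[: k - 1] if draft.circular \
        else draft.sequence
    L = len(draft)
    draft_counts = []
    positions = []
    for i in range(L if draft.circular else L - k + 1):
        kmer = doubled[i : i + k]
        c = counts.get(min(kmer, reverse_complement(kmer)), 0)
        draft_counts.append(c)
        positions.append(i)
    nonzero = [c for c in draft_counts if c > 0]
    if expected_depth is None:
        if not nonzero:
            raise ValidationError("no draft k-mer observed in the reads")
        modal = Counter(nonzero).most_common(1)[0][0]
    else:
        modal = expected_depth
    threshold = fold * modal
    flagged = set()
    flagged_pos = []
    for i, c in zip(positions, draft_counts):
        if c >= threshold and c > 0:
            kmer = doubled[i : i + k]
            flagged.add(min(kmer, reverse_complement(kmer)))
            flagged_pos.append(i)
    regions: list[tuple[int, int]] = []
    for p in flagged_pos:
        if regions and p <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], p + k))
        else:
            regions.append((p, p + k))
    return RepeatScanResult(flagged_kmers=flagged, regions=regions,
                            modal_count=int(modal), n_too_short=n_too_short)


def decontaminate(reads: ReadSet, contaminant: MitoGenome,
                  identity_threshold: float = 0.90) -> tuple[ReadSet, ReadSet]:
    """Purge reads matching a contaminant reference; returns (kept, purged)."""
    if not contaminant.sequence:
        raise ValidationError("empty contaminant reference")
    kept, purged = [], []
    for read in reads:
        hit = align_identity(read.sequence, contaminant)
        (purged if hit.identity >= identity_threshold else kept).append(read)
    return ReadSet(kept), ReadSet(purged)
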