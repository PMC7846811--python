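"""Data model and readers/writers shared by every analysis stage.

Coordinates are 0-based half-open internally; the tab-delimited annotation
format on disk is 1-based inclusive (GFF convention).  Features of a circular
molecule that span the origin are stored unwrapped: ``end`` may exceed the
sequence length by the wrapped amount, and accessors return the concatenated
subsequence.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_KINDS = ("CDS", "tRNA", "rRNA", "NC")
VALID_STRANDS = ("heavy", "light")
VALID_PLATFORMS = ("short_pe", "long")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature on a (possibly circular) mitochondrial molecule."""

    name: str
    kind: str  # CDS | tRNA | rRNA | NC
    start: int  # 0-based
    end: int  # half-open; may exceed genome length for origin-spanning features
    strand: str = "heavy"
    copy_index: int = 1
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.kind == "CDS" and self.end - self.start < 3:
            raise ValidationError(f"{self.name}: CDS shorter than one codon")
        if self.copy_index < 1:
            raise ValidationError(f"{self.name}: copy_index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.copy_index)


@dataclass
class MitoGenome:
    """A circular mitochondrial molecule with its gene annotations."""

    id: str
    sequence: str
    circular: bool = True
    annotations: list[GeneAnnotation] = field(default_factory=list)
    molecule_tag: Optional[str] = None  # M1 | M2 | other

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        seen: set[tuple[str, int]] = set()
        for ann in self.annotations:
            if ann.key in seen:
                raise ValidationError(
                    f"{self.id}: duplicate annotation {ann.name} copy {ann.copy_index}"
                )
            seen.add(ann.key)
            limit = 2 * len(self.sequence) if self.circular else len(self.sequence)
            if ann.start >= len(self.sequence) or ann.end > limit:
                raise ValidationError(
                    f"{self.id}: annotation {ann.name} outside [0, {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, ann: GeneAnnotation) -> str:
        """Subsequence of a feature, wrapping the circular origin if needed.

        Light-strand features are returned reverse-complemented (i.e. in
        their own reading orientation).
        """
        seq = self.sequence
        if ann.end <= len(seq):
            sub = seq[ann.start : ann.end]
        elif self.circular:
            sub = seq[ann.start :] + seq[: ann.end - len(seq)]
        else:
            raise ValidationError(f"{self.id}: {ann.name} wraps a linear sequence")
        if ann.strand == "light":
            sub = reverse_complement(sub)
        return sub

    def get_annotation(self, name: str, copy_index: int = 1) -> GeneAnnotation:
        for ann in self.annotations:
            if ann.name == name and ann.copy_index == copy_index:
                return ann
        raise KeyError(f"{self.id}: no annotation {name} copy {copy_index}")

    def with_tag(self, tag: str) -> "MitoGenome":
        out = MitoGenome(
            id=self.id,
            sequence=self.sequence,
            circular=self.circular,
            annotations=list(self.annotations),
            molecule_tag=tag,
        )
        return out


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: Optional[str] = None
    platform: str = "long"
    mate_id: Optional[str] = None
    true_origin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.platform not in VALID_PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValidationError(f"{self.id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate read ids")
        by_id = {r.id: r for r in self.reads}
        for r in self.reads:
            if r.mate_id is not None:
                mate = by_id.get(r.mate_id)
                if mate is None or mate.mate_id != r.id:
                    raise ValidationError(f"{r.id}: non-reciprocal mate pairing")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def subset(self, ids: Iterable[str]) -> "ReadSet":
        keep = set(ids)
        return ReadSet([r for r in self.reads if r.id in keep])


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValidationError("names/rows length mismatch")
        if len(self.rows) < 2:
            raise ValidationError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [normalize_sequence(r, allow_gap=True) for r in self.rows]
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate row names")

    @property
    def site_count(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no alignment row named {name!r}") from None

    def drop_columns(self, cols: set[int]) -> "MultipleAlignment":
        keep = [i for i in range(self.site_count) if i not in cols]
        return MultipleAlignment(
            names=list(self.names),
            rows=["".join(r[i] for i in keep) for r in self.rows],
        )


@dataclass
class ExclusionMask:
    """Half-open intervals to exclude; row_name 'ALL' applies to every row."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, start, end in self.intervals:
            if start < 0 or end < start:
                raise ValidationError(f"bad mask interval ({name}, {start}, {end})")

    def excluded_columns(self, aln: MultipleAlignment) -> set[int]:
        """Alignment columns excluded for any listed row (or ALL).

        Interval coordinates are *ungapped* positions in the named row; for
        row 'ALL' they are alignment column indices directly.
        """
        cols: set[int] = set()
        for name, start, end in self.intervals:
            if name == "ALL":
                cols.update(range(start, min(end, aln.site_count)))
                continue
            row = aln.row(name)
            pos = 0  # ungapped position
            for col, ch in enumerate(row):
                if ch == "-":
                    continue
                if start <= pos < end:
                    cols.add(col)
                pos += 1
        return cols


# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")


def normalize_sequence(seq: str, allow_gap: bool = False) -> str:
    s = seq.upper().replace("U", "T")
    alphabet = set("ACGTN") | ({"-"} if allow_gap else set())
    bad = set(s) - alphabet - set("RYKMSWBDHV")
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased DNA sequence) pairs."""
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise ParseError(f"{path}: line {first_bad}: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(normalize_sequence(seq)), id=name, description="")
        for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_alignment_fasta(path) -> MultipleAlignment:
    path = Path(path)
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq))
    if not names:
        raise ParseError(f"{path}: no records")
    return MultipleAlignment(names=names, rows=rows)


def write_alignment_fasta(path, aln: MultipleAlignment) -> None:
    write_fasta(path, list(zip(aln.names, aln.rows)))


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path, platform: str = "long") -> ReadSet:
    """Read 4-line FASTQ records into a ReadSet; platform supplied by caller."""
    path = Path(path)
    reads = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.strip():
                continue
            if not header.startswith("@"):
                raise ParseError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError(f"{path}: line {lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: line {lineno}: sequence/quality length mismatch"
                )
            reads.append(
                Read(
                    id=header[1:].split()[0],
                    sequence=normalize_sequence(seq),
                    quality=qual,
                    platform=platform,
                )
            )
    return ReadSet(reads)


def write_fastq(path, readset: ReadSet) -> None:
    with open(path, "w") as fh:
        for r in readset:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# annotation tables (tab-delimited, 1-based inclusive on disk)

_ANN_COLUMNS = ("seqid", "name", "kind", "start", "end", "strand", "copy_index")


def read_annotations(path) -> dict[str, list[GeneAnnotation]]:
    """Read a tab-delimited annotation table keyed by seqid.

    On-disk coordinates are 1-based inclusive; values are converted to the
    internal 0-based half-open convention.  A feature wrapping the circular
    origin is written with end < start and is unwrapped here (end becomes
    start-relative beyond the stated end, to be interpreted modulo the genome
    length by the accessor).
    """
    path = Path(path)
    out: dict[str, list[GeneAnnotation]] = {}
    genome_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("#length"):
                    _, seqid, length = line.split("\t")
                    genome_lengths[seqid] = int(length)
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >= 6 columns")
            seqid, name, kind, start_s, end_s, strand = parts[:6]
            copy_index = int(parts[6]) if len(parts) > 6 and parts[6] else 1
            pseudo = len(parts) > 7 and parts[7].strip().lower() in ("1", "true", "pseudo")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            start = start1 - 1
            end = end1
            if end <= start:  # wraps the circular origin
                length = genome_lengths.get(seqid)
                if length is None:
                    raise ParseError(
                        f"{path}: line {lineno}: origin-spanning feature needs a "
                        f"'#length\\t{seqid}\\t<bp>' directive"
                    )
                end = end1 + length
            ann = GeneAnnotation(
                name=name, kind=kind, start=start, end=end,
                strand=strand, copy_index=copy_index, pseudo=pseudo,
            )
            bucket = out.setdefault(seqid, [])
            if any(b.key == ann.key for b in bucket):
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate ({name}, {copy_index})"
                )
            bucket.append(ann)
    return out


def write_annotations(path, table: dict[str, list[GeneAnnotation]],
                      genome_lengths: Optional[dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ANN_COLUMNS) + "\n")
        genome_lengths = genome_lengths or {}
        for seqid, length in genome_lengths.items():
            fh.write(f"#length\t{seqid}\t{length}\n")
        for seqid, anns in table.items():
            length = genome_lengths.get(seqid)
            for a in anns:
                start1 = a.start + 1
                end1 = a.end
                if length is not None and a.end > length:
                    end1 = a.end - length  # re-wrap for the text form
                row = [seqid, a.name, a.kind, str(start1), str(end1), a.strand,
                       str(a.copy_index)]
                if a.pseudo:
                    row.append("pseudo")
                fh.write("\t".join(row) + "\n")
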