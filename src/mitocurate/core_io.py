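"""Shared data model and I/O for circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout (GenBank convention).  A
feature whose ``end`` is smaller than its ``start`` wraps across the
origin of the circular chromosome.  All features live on the sense
strand: triclad mitochondrial genomes are transcribed from a single
strand, and antisense annotations are rejected at the boundary.
BED/bedGraph I/O converts to 0-based half-open coordinates at the edge
of the package and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "GeneAnnotation",
    "AnnotationTable",
    "AlphabetError",
    "FormatError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "write_gff",
    "read_gff",
    "write_bed",
    "circular_length",
    "circular_positions",
    "circular_overlap",
    "signed_gap",
    "circular_distance",
]

_ALPHABET = set("ACGTN")

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ncRNA", "ORF")


class FormatError(ValueError):
    """Malformed or empty input file."""


class AlphabetError(ValueError):
    """Sequence residue outside the A/C/G/T/N alphabet."""


class ValidationError(ValueError):
    """Annotation inconsistent with the genome or the data model."""


# ---------------------------------------------------------------------------
# circular coordinate arithmetic
# ---------------------------------------------------------------------------

def circular_length(start: int, end: int, genome_length: int) -> int:
    """Number of bases in the 1-based inclusive circular interval [start, end].

    ``end < start`` denotes an interval wrapping across the origin.
    """
    if not (1 <= start <= genome_length and 1 <= end <= genome_length):
        raise ValidationError(
            f"interval ({start}, {end}) out of range for genome of "
            f"length {genome_length}"
        )
    if end >= start:
        return end - start + 1
    return genome_length - start + 1 + end


def circular_positions(start: int, end: int, genome_length: int):
    """Yield every 1-based position covered by the circular interval."""
    n = circular_length(start, end, genome_length)
    for i in range(n):
        yield (start - 1 + i) % genome_length + 1


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Unsigned circular distance between two 1-based positions."""
    d = abs(a - b) % genome_length
    return min(d, genome_length - d)


def _linear_parts(start: int, end: int, genome_length: int):
    if end >= start:
        return [(start, end)]
    return [(start, genome_length), (1, end)]


def circular_overlap(start1: int, end1: int, start2: int, end2: int,
                     genome_length: int) -> int:
    """Number of bases shared by two 1-based inclusive circular intervals."""
    total = 0
    for s1, e1 in _linear_parts(start1, end1, genome_length):
        for s2, e2 in _linear_parts(start2, end2, genome_length):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def signed_gap(prev_end: int, start: int, genome_length: int) -> int:
    """Signed number of bases between a feature ending at ``prev_end`` and a
    downstream position ``start``; 0 means directly adjacent, negative means
    ``start`` lies inside the upstream feature (overlap).

    The result is folded into ``[-L/2, L/2)`` so that small overlaps across
    the origin come out negative rather than nearly genome-sized.
    """
    L = genome_length
    return (start - prev_end - 1 + L // 2) % L - L // 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A circular, single-sequence mitochondrial chromosome."""

    id: str
    sequence: str
    species: str = ""
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValidationError(f"genome {self.id!r} has empty sequence")
        for i, c in enumerate(seq):
            if c not in _ALPHABET:
                raise AlphabetError(
                    f"genome {self.id!r}: residue {c!r} at position {i + 1} "
                    "is not one of A/C/G/T/N"
                )
        if not self.species:
            object.__setattr__(self, "species", self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the circular 1-based inclusive interval [start, end]."""
        L = len(self.sequence)
        if end >= start:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class GeneAnnotation:
    """One sense-strand feature in 1-based inclusive circular coordinates."""

    gene: str
    type: str
    start: int
    end: int
    strand: str = "+"
    start_codon: str | None = None

    def __post_init__(self):
        if self.type not in FEATURE_TYPES:
            raise ValidationError(
                f"feature {self.gene!r}: unknown type {self.type!r}"
            )
        if self.strand != "+":
            raise ValidationError(
                f"feature {self.gene!r}: strand {self.strand!r} unsupported; "
                "these genomes are transcribed from a single strand"
            )
        if self.start < 1 or self.end < 1:
            raise ValidationError(
                f"feature {self.gene!r}: coordinates are 1-based, got "
                f"({self.start}, {self.end})"
            )

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        return circular_length(self.start, self.end, genome_length)

    def overlap(self, start: int, end: int, genome_length: int) -> int:
        """Number of bases this feature shares with the interval [start, end]."""
        return circular_overlap(self.start, self.end, start, end, genome_length)


@dataclass
class AnnotationTable:
    """Ordered gene features for one genome, sorted by start position."""

    genome_id: str
    features: list[GeneAnnotation] = field(default_factory=list)
    genome_length: int | None = None

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        coding = [f.gene for f in self.features if f.type == "CDS"]
        dupes = {g for g in coding if coding.count(g) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate protein-coding gene labels: {sorted(dupes)}"
            )

    def validate_against(self, genome: Genome) -> None:
        L = len(genome)
        for f in self.features:
            if f.start > L or f.end > L:
                raise ValidationError(
                    f"feature {f.gene!r} ({f.start}, {f.end}) exceeds genome "
                    f"length {L}"
                )
            if f.length(L) >= L:
                raise ValidationError(
                    f"feature {f.gene!r} covers the full circle"
                )
        self.genome_length = L

    def of_type(self, *types: str) -> list[GeneAnnotation]:
        return [f for f in self.features if f.type in types]

    def get(self, gene: str) -> GeneAnnotation:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Genome]:
    """Read a (multi-)FASTA file into Genome records.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased and checked against the A/C/G/T/N alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        desc = rec.description[len(rec.id):].strip()
        genomes.append(Genome(id=rec.id, sequence=str(rec.seq), species=desc or rec.id))
    return genomes


def write_fasta(genomes: list[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            header = g.id if g.species in ("", g.id) else f"{g.id} {g.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation tables (TSV)
# ---------------------------------------------------------------------------

def read_annotation_table(path, genome: Genome) -> AnnotationTable:
    """Read a TSV of features (columns: gene, type, start, end[, start_codon]).

    Coordinates are 1-based inclusive; ``end < start`` marks a feature that
    wraps across the origin.  A strand column, if present, must be "+".
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "type": str})
    required = {"gene", "type", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if pd.isna(strand):
            strand = "+"
        codon = getattr(row, "start_codon", None)
        if codon is not None and pd.isna(codon):
            codon = None
        start, end = int(row.start), int(row.end)
        if start < 1 or end < 1:
            raise ValidationError(
                f"{path}: feature {row.gene!r} has non-positive coordinate "
                f"({start}, {end}); coordinates are 1-based"
            )
        feats.append(
            GeneAnnotation(
                gene=str(row.gene), type=str(row.type), start=start, end=end,
                strand=str(strand), start_codon=codon,
            )
        )
    table = AnnotationTable(genome_id=genome.id, features=feats)
    table.validate_against(genome)
    return table


def write_annotation_table(table: AnnotationTable, path) -> None:
    rows = [
        {
            "gene": f.gene, "type": f.type, "start": f.start, "end": f.end,
            "strand": f.strand, "start_codon": f.start_codon or "",
        }
        for f in table.features
    ]
    pd.DataFrame(
        rows, columns=["gene", "type", "start", "end", "strand", "start_codon"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_GFF_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
             "ncRNA": "ncRNA", "ORF": "open_reading_frame"}


def write_gff(table: AnnotationTable, path) -> None:
    """Write GFF3; origin-wrapping features become two parts sharing an ID."""
    if table.genome_length is None:
        raise ValidationError("table must be validated against its genome first")
    L = table.genome_length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {table.genome_id} 1 {L}\n")
        for i, f in enumerate(table.features):
            attrs = f"ID={table.genome_id}.f{i};Name={f.gene};gene_type={f.type}"
            if f.start_codon:
                attrs += f";start_codon={f.start_codon}"
            parts = [(f.start, L), (1, f.end)] if f.wraps else [(f.start, f.end)]
            for s, e in parts:
                cols = [table.genome_id, "mitocurate", _GFF_TYPE[f.type],
                        str(s), str(e), ".", "+", ".", attrs]
                fh.write("\t".join(cols) + "\n")


def read_gff(path, genome: Genome) -> AnnotationTable:
    """Read GFF3 written by :func:`write_gff`, merging split wrapped features."""
    by_id: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: bad GFF line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            fid = attrs["ID"]
            if fid not in by_id:
                by_id[fid] = {"attrs": attrs, "parts": []}
                order.append(fid)
            by_id[fid]["parts"].append((int(cols[3]), int(cols[4])))
    rev_type = {v: k for k, v in _GFF_TYPE.items()}
    feats = []
    for fid in order:
        entry = by_id[fid]
        parts = sorted(entry["parts"])
        if len(parts) == 1:
            start, end = parts[0]
        else:  # wrapped: (1, end) and (start, L)
            (_, end), (start, _) = parts
        a = entry["attrs"]
        feats.append(GeneAnnotation(
            gene=a["Name"], type=rev_type[a.get("gene_type", "CDS")]
            if a.get("gene_type") in rev_type else a["gene_type"],
            start=start, end=end, start_codon=a.get("start_codon"),
        ))
    table = AnnotationTable(genome_id=genome.id, features=feats)
    table.validate_against(genome)
    return table


def write_bed(intervals, path, genome_id: str, genome_length: int,
              names=None, scores=None) -> None:
    """Write 1-based inclusive circular intervals as BED6 (0-based half-open).

    Wrapping intervals are split into two BED lines with the same name.
    """
    names = names or [f"region{i + 1}" for i in range(len(intervals))]
    scores = scores if scores is not None else [0] * len(intervals)
    with open(path, "w") as fh:
        for (start, end), name, score in zip(intervals, names, scores):
            parts = ([(start, genome_length), (1, end)] if end < start
                     else [(start, end)])
            for s, e in parts:
                fh.write(f"{genome_id}\t{s - 1}\t{e}\t{name}\t{int(score)}\t+\n")
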