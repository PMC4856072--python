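"""Sense-strand ORF scanning under the echinoderm/flatworm mitochondrial code.

The genetic code here is NCBI/ENA translation table 9 (AAA -> Asn,
AGA/AGG -> Ser, TGA -> Trp; stops TAA/TAG), shipped as a literal codon map.
The default initiator set extends the canonical {ATG, GTG} with TTG, the
noncanonical start codon that cross-species homology supports in triclad
mitochondrial genomes.

ORFs are *stop-to-stop* maximal segments rather than start-anchored ones:
start-codon choice is deferred to the cross-species refinement stage, which
needs to see homology extending upstream of any particular candidate start.
Scanning is circular — the sequence is conceptually doubled so segments may
wrap the origin — and a segment can never exceed the genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core_io import Genome, GeneAnnotation, circular_overlap

__all__ = ["CodonTable", "TABLE_9", "Orf", "translate", "scan_orfs",
           "orf_for_locus", "LocusNotFoundError"]

# NCBI/ENA translation table 9 (echinoderm & flatworm mitochondrial),
# written out in full as data.
_TABLE9_CODON_TO_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "N", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "S", "AGG": "S",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class CodonTable:
    """A codon -> amino acid map plus the set of accepted initiator codons."""

    code_id: str = "9+TTG"
    codon_to_aa: dict = field(default_factory=lambda: dict(_TABLE9_CODON_TO_AA))
    start_codons: frozenset = frozenset({"ATG", "GTG", "TTG"})

    def __post_init__(self):
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"codon table must map all 64 codons, got {len(self.codon_to_aa)}"
            )
        stops = self.stop_codons
        if not stops:
            raise ValueError("codon table has no stop codons")
        bad = set(self.start_codons) & stops
        if bad:
            raise ValueError(f"start codons {sorted(bad)} are stop codons")
        object.__setattr__(self, "start_codons", frozenset(self.start_codons))

    @property
    def stop_codons(self) -> set:
        return {c for c, aa in self.codon_to_aa.items() if aa == "*"}

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def synonymous_codons(self, aa: str) -> list[str]:
        return sorted(c for c, a in self.codon_to_aa.items() if a == aa)


TABLE_9 = CodonTable()


def translate(seq: str, table: CodonTable = TABLE_9,
              as_initiator: bool = False) -> str:
    """Translate a nucleotide string codon by codon.

    Stops are rendered "*" and do not terminate translation (the caller
    decides what a stop means).  Codons containing N translate to "X".
    With ``as_initiator`` the first codon is rendered "M" when it is a
    member of the table's initiator set (initiator tRNA carries Met).
    A trailing partial codon is dropped with a warning.
    """
    seq = seq.upper()
    if len(seq) % 3:
        warnings.warn(
            f"sequence length {len(seq)} not divisible by 3; "
            "dropping trailing partial codon", stacklevel=2,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = table.codon_to_aa.get(codon, "X")
        if i == 0 and as_initiator and codon in table.start_codons:
            aa = "M"
        out.append(aa)
    return "".join(out)


@dataclass
class Orf:
    """A maximal sense-strand stop-to-stop segment (stop codon excluded).

    ``start``/``end`` are 1-based inclusive genome coordinates of the first
    and last base of the segment; ``end < start`` means the ORF wraps the
    origin.  ``candidate_starts`` lists every in-frame initiator-codon
    occurrence 5'->3' as (genome position, codon).
    """

    genome_id: str
    frame: int
    start: int
    end: int
    protein: str
    candidate_starts: list = field(default_factory=list)
    chosen_start: int | None = None
    no_stop: bool = False

    def __len__(self) -> int:
        return len(self.protein)

    def aa_index_of(self, position: int, genome_length: int) -> int:
        """0-based residue index of the codon starting at ``position``."""
        off = (position - self.start) % genome_length
        if off % 3:
            raise ValueError(f"position {position} not in frame with ORF start "
                             f"{self.start}")
        idx = off // 3
        if idx >= len(self.protein):
            raise ValueError(f"position {position} outside ORF")
        return idx


def scan_orfs(genome: Genome, table: CodonTable = TABLE_9,
              min_len: int = 80) -> list[Orf]:
    """Find every circular stop-to-stop ORF of at least ``min_len`` residues.

    All three sense frames are scanned across the origin.  If a frame
    contains no stop codon at all, a single segment capped at the full
    frame length is emitted with ``no_stop=True``.
    """
    L = len(genome)
    doubled = genome.sequence + genome.sequence
    seen: set[int] = set()
    orfs: list[Orf] = []
    max_codons = L // 3

    for f in range(3):
        codon_pos = list(range(f, 2 * L - 2, 3))
        codons = [doubled[p : p + 3] for p in codon_pos]
        stop_idx = [i for i, c in enumerate(codons) if table.is_stop(c)]

        segments = []  # (first codon index, n codons, no_stop)
        if not stop_idx:
            # whole circular frame is stop-free: cap at one genome length
            segments.append((0, min(max_codons, len(codons)), True))
        else:
            for a, b in zip(stop_idx, stop_idx[1:]):
                if b - a > 1:
                    segments.append((a + 1, b - a - 1, False))

        for i0, ncod, no_stop in segments:
            if ncod < 1 or ncod > max_codons:
                continue
            p0 = codon_pos[i0]
            key = p0 % L
            if key in seen:
                continue
            seen.add(key)
            if ncod < min_len:
                continue
            start = key + 1
            end = (p0 + 3 * ncod - 1) % L + 1
            protein = translate(doubled[p0 : p0 + 3 * ncod], table)
            cands = []
            for j in range(ncod):
                codon = doubled[p0 + 3 * j : p0 + 3 * j + 3]
                if codon in table.start_codons:
                    cands.append(((p0 + 3 * j) % L + 1, codon))
            orfs.append(Orf(
                genome_id=genome.id, frame=key % 3, start=start, end=end,
                protein=protein, candidate_starts=cands, no_stop=no_stop,
            ))

    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


class LocusNotFoundError(LookupError):
    """No scanned ORF overlaps the requested annotated locus."""


def orf_for_locus(orfs: list[Orf], feature: GeneAnnotation,
                  genome_length: int) -> Orf:
    """The ORF with maximal circular overlap with ``feature``.

    Ties are broken in favour of the longer ORF.
    """
    best, best_key = None, None
    for orf in orfs:
        ov = circular_overlap(orf.start, orf.end, feature.start, feature.end,
                              genome_length)
        if ov <= 0:
            continue
        key = (ov, len(orf.protein))
        if best_key is None or key > best_key:
            best, best_key = orf, key
    if best is None:
        raise LocusNotFoundError(
            f"no ORF overlaps {feature.gene} ({feature.start}-{feature.end})"
        )
    return best
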