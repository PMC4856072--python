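"""Cross-species start-codon refinement.

Given stop-to-stop ORFs from a panel of related mitochondrial genomes, this
module (1) assigns each species' ORFs to reference genes by exact local
protein alignment, (2) multi-aligns each homolog group, and (3) chooses a
start codon for every member by scoring each in-frame initiator candidate:
conserved homology should extend down from the chosen start (not upstream
of it), and the start should not run the gene into its upstream neighbour.

The homology search is exact Smith-Waterman with BLOSUM62 and affine gaps
(open 11, extend 1 — the classic protein-search defaults), with a raw-score
acceptance threshold instead of an E-value: panels here hold a handful of
sequences, so database-size statistics buy nothing.  The multiple alignment
is a deterministic center-star progressive alignment ("once a gap, always a
gap"), which is entirely adequate for small groups of closely related
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import AnnotationTable, signed_gap
from .orf_engine import Orf

__all__ = ["HomologGroup", "StartCall", "local_align", "group_homologs",
           "multi_align", "select_start", "refine_starts"]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)

# initiator preference used only to break exact score ties
_CODON_RANK = {"ATG": 0, "GTG": 1, "TTG": 2}


def _sanitize(seq: str) -> str:
    """Map residues outside the substitution-matrix alphabet to X."""
    return "".join(c if c in _ALPHABET else "X" for c in seq.upper())


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -12.0   # cost 11 + k for a gap of length k
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    if mode == "global":
        # end gaps free: N/C-terminal extensions should not be punished
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def local_align(a: str, b: str) -> tuple[float, tuple[str, str]]:
    """Optimal Smith-Waterman local alignment (BLOSUM62, gap 11/1).

    Returns the score and one optimal aligned pair (with "-" gaps).  The
    first alignment Biopython enumerates is taken, which is deterministic
    for fixed inputs.  An all-mismatch pair has score 0 and empty strings.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _make_aligner("local")
    a, b = _sanitize(a), _sanitize(b)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return 0.0, ("", "")
    aln = alignments[0]
    return float(alignments.score), (str(aln[0]), str(aln[1]))


def local_score(a: str, b: str) -> float:
    """Smith-Waterman score only (cheaper than materialising an alignment)."""
    if not a or not b:
        raise ValueError("local_score requires non-empty sequences")
    aligner = _make_aligner("local")
    return float(aligner.score(_sanitize(a), _sanitize(b)))


@dataclass
class HomologGroup:
    """One reference gene with its best-matching ORF from each species."""

    gene: str
    members: dict = field(default_factory=dict)   # species -> Orf
    scores: dict = field(default_factory=dict)    # species -> raw SW score
    alignment: dict | None = None                 # species -> aligned row
    column_occupancy: list | None = None
    unalignable: bool = False
    absences: list = field(default_factory=list)  # species with no hit

    @property
    def n_members(self) -> int:
        return len(self.members)


def group_homologs(orf_sets: dict, reference: dict,
                   min_score: float = 50.0) -> list[HomologGroup]:
    """Assign each species' ORFs to reference genes by best local alignment.

    ``orf_sets`` maps species -> list of Orf; ``reference`` maps gene label
    -> reference protein sequence.  Each ORF joins at most one group (its
    highest-scoring reference gene), and each group keeps at most one ORF
    per species (the highest-scoring one).  Groups that end up with fewer
    than two members are flagged ``unalignable``.  Species order does not
    affect the result.
    """
    groups = {gene: HomologGroup(gene=gene) for gene in sorted(reference)}
    for species in sorted(orf_sets):
        # best reference gene per ORF, then best ORF per gene
        per_gene: dict[str, tuple[float, int, Orf]] = {}
        for idx, orf in enumerate(orf_sets[species]):
            best_gene, best_score = None, min_score
            for gene in sorted(reference):
                s = local_score(orf.protein, reference[gene])
                if s > best_score or (s == best_score and best_gene is None):
                    best_gene, best_score = gene, s
            if best_gene is None:
                continue
            cur = per_gene.get(best_gene)
            if cur is None or (best_score, -cur[1]) > (cur[0], -idx):
                per_gene[best_gene] = (best_score, idx, orf)
        for gene, (score, _idx, orf) in per_gene.items():
            groups[gene].members[species] = orf
            groups[gene].scores[species] = score
    all_species = sorted(orf_sets)
    out = []
    for gene in sorted(groups):
        g = groups[gene]
        g.absences = [sp for sp in all_species if sp not in g.members]
        g.unalignable = g.n_members < 2
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

def _pairwise_global(center: str, other: str) -> tuple[str, str]:
    aligner = _make_aligner("global")
    aln = aligner.align(_sanitize(center), _sanitize(other))[0]
    return str(aln[0]), str(aln[1])


def _merge_onto_center(center: str, rows: list[tuple[str, str]]):
    """Merge pairwise (center, other) alignments into one MSA.

    Classic center-star merge: the union of gap positions inserted into the
    center across all pairwise alignments defines the master center row;
    once a gap is introduced it is never removed.
    """
    # per-alignment: list of gaps inserted after each center residue index
    n = len(center)
    # master gap counts between center residues (index 0..n slots)
    master = [0] * (n + 1)
    parsed = []
    for c_row, o_row in rows:
        gaps = [0] * (n + 1)
        ci = 0
        for ch in c_row:
            if ch == "-":
                gaps[ci] += 1
            else:
                ci += 1
        parsed.append((gaps, c_row, o_row))
        for i in range(n + 1):
            master[i] = max(master[i], gaps[i])

    def expand_center() -> str:
        out = []
        for i in range(n + 1):
            out.append("-" * master[i])
            if i < n:
                out.append(center[i])
        return "".join(out)

    def expand_other(gaps, c_row, o_row) -> str:
        # walk the pairwise alignment, padding each inter-residue slot
        out = []
        pos = 0  # index into pairwise rows
        for i in range(n + 1):
            slot = gaps[i]
            out.append(o_row[pos : pos + slot])
            out.append("-" * (master[i] - slot))
            pos += slot
            if i < n:
                out.append(o_row[pos])  # column of center residue i
                pos += 1
        return "".join(out)

    center_row = expand_center()
    other_rows = [expand_other(*p) for p in parsed]
    return center_row, other_rows


def multi_align(group: HomologGroup) -> HomologGroup:
    """Center-star progressive alignment of a homolog group (in place).

    The center is the member maximising its summed pairwise score against
    the others (ties broken by species name); every other member is
    globally aligned to the center with free end gaps, and the pairwise
    alignments are merged "once a gap, always a gap".  Column occupancy is
    the fraction of non-gap rows per column.
    """
    if group.n_members < 2:
        raise ValueError(f"group {group.gene}: need >= 2 members to align")
    species = sorted(group.members)
    seqs = {sp: group.members[sp].protein for sp in species}
    totals = {}
    for sp in species:
        totals[sp] = sum(local_score(seqs[sp], seqs[o])
                         for o in species if o != sp)
    center_sp = max(species, key=lambda sp: (totals[sp], sp))
    others = [sp for sp in species if sp != center_sp]
    pairwise = [_pairwise_global(seqs[center_sp], seqs[sp]) for sp in others]
    center_row, other_rows = _merge_onto_center(seqs[center_sp], pairwise)
    alignment = {center_sp: center_row}
    alignment.update(dict(zip(others, other_rows)))
    width = len(center_row)
    assert all(len(r) == width for r in alignment.values())
    n = len(species)
    occupancy = [
        sum(1 for sp in species if alignment[sp][j] != "-") / n
        for j in range(width)
    ]
    group.alignment = alignment
    group.column_occupancy = occupancy
    return group


# ---------------------------------------------------------------------------
# start selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StartCall:
    """A chosen start codon for one gene in one species."""

    species: str
    gene: str
    position: int           # 1-based genome coordinate of the codon
    codon: str
    upstream_gap: int       # bases to the upstream feature; negative = overlap
    conserved_columns_covered: int
    score: float


def _aa_index_to_column(row: str) -> list[int]:
    """Map residue index -> alignment column for one gapped row."""
    cols = []
    for j, ch in enumerate(row):
        if ch != "-":
            cols.append(j)
    return cols


def _upstream_feature(table: AnnotationTable, gene: str, genome_length: int,
                      position: int):
    """The annotated feature whose end most closely precedes ``position``."""
    best, best_d = None, None
    for f in table.features:
        if f.gene == gene:
            continue
        d = (position - f.end - 1) % genome_length  # 0 = directly adjacent
        if best_d is None or d < best_d:
            best, best_d = f, d
    return best


def select_start(group: HomologGroup, tables: dict,
                 occupancy_threshold: float = 0.5,
                 overlap_penalty: float = 1.0) -> list[StartCall]:
    """Choose each member's start codon from its in-frame candidates.

    Candidate ``c`` scores (number of alignment columns with occupancy >=
    ``occupancy_threshold`` lying at or downstream of c's column) minus
    ``overlap_penalty`` times the bases by which c overlaps the upstream
    annotated feature.  Ties go to ATG over GTG over TTG, then to the most
    upstream position.  Members with no candidate start are skipped.
    """
    if group.alignment is None:
        raise ValueError(f"group {group.gene} must be aligned first")
    calls = []
    conserved_cols = [j for j, occ in enumerate(group.column_occupancy)
                      if occ >= occupancy_threshold]
    for species in sorted(group.members):
        orf = group.members[species]
        if not orf.candidate_starts:
            continue
        table = tables[species]
        L = table.genome_length
        row = group.alignment[species]
        aa_cols = _aa_index_to_column(row)
        best = None
        for pos, codon in orf.candidate_starts:
            aa_idx = orf.aa_index_of(pos, L)
            col = aa_cols[aa_idx]
            covered = sum(1 for j in conserved_cols if j >= col)
            upstream = _upstream_feature(table, group.gene, L, pos)
            if upstream is not None:
                gap = signed_gap(upstream.end, pos, L)
            else:
                gap = 0
            overlap = max(0, -gap)
            score = covered - overlap_penalty * overlap
            rank = _CODON_RANK.get(codon, 3)
            # maximise score; then prefer ATG > GTG > TTG; then most upstream
            key = (-score, rank, aa_idx)
            if best is None or key < best[0]:
                best = (key, pos, codon, gap, covered, score)
        _, pos, codon, gap, covered, score = best
        calls.append(StartCall(
            species=species, gene=group.gene, position=pos, codon=codon,
            upstream_gap=gap, conserved_columns_covered=covered, score=score,
        ))
    return calls


def refine_starts(orf_sets: dict, reference: dict, tables: dict,
                  min_score: float = 50.0, occupancy_threshold: float = 0.5,
                  overlap_penalty: float = 1.0) -> list[StartCall]:
    """End-to-end refinement: group, align, and call starts for a panel."""
    calls = []
    for group in group_homologs(orf_sets, reference, min_score=min_score):
        if group.unalignable:
            continue
        multi_align(group)
        calls.extend(select_start(group, tables,
                                  occupancy_threshold=occupancy_threshold,
                                  overlap_penalty=overlap_penalty))
    return calls
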