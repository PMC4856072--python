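"""Noncoding-region cataloguing and novel-ORF discovery.

Triclad mitochondrial genomes differ enormously in the length of their
intergenic noncoding regions (from a few hundred bases to >11 kb), and some
of those regions are transcribed and harbour short ORFs — most notably a
positionally conserved ORF directly after nad2 whose transmembrane /
signal-peptide-like architecture resembles the otherwise missing atp8.

The catalogue treats a noncoding region as a maximal circular interval free
of CDS and rRNA features; tRNAs falling inside are recorded as interrupting
features and, by default, their bases are excluded from the reported region
length (a region "interrupted by a single tRNA" is still one region).

Membrane architecture is assessed with a Kyte-Doolittle sliding-window
hydropathy scan (window 19, cutoff 1.6 — the standard constants for
transmembrane detection) plus a rule-based signal-peptide-like heuristic
(positive residue among the first five, then a hydrophobic stretch within
the first thirty).  Both are explicit, documented heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import (AnnotationTable, Genome, ValidationError,
                      circular_length)
from .orf_engine import CodonTable, Orf, TABLE_9, translate

__all__ = [
    "NoncodingRegion", "CandidateOrf", "KYTE_DOOLITTLE",
    "noncoding_catalog", "survey_gene_lengths", "discover_candidate_orfs",
    "hydropathy_tm", "signal_like_nterm",
]

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class NoncodingRegion:
    """A maximal circular interval free of CDS/rRNA features."""

    start: int
    end: int
    length: int                       # bases, minus interrupting tRNAs
    span: int                         # bases including interrupting tRNAs
    interrupting_features: tuple
    flanking_genes: tuple             # (upstream label, downstream label)
    klass: str                        # "long" or "short"


@dataclass
class CandidateOrf:
    """A start-anchored ORF discovered inside a noncoding/transcribed region."""

    orf: Orf
    after_gene: str
    distance_from_after_gene: int
    tm_segments: list = field(default_factory=list)
    has_signal_like_nterm: bool = False


def noncoding_catalog(table: AnnotationTable, genome: Genome,
                      long_threshold: int = 500,
                      include_trna_length: bool = False) -> list[NoncodingRegion]:
    """Catalogue the maximal intervals free of CDS and rRNA features.

    tRNAs inside an interval are listed as interrupting features; their
    bases are excluded from ``length`` unless ``include_trna_length`` is
    set (``span`` always includes them).  Regions of at least
    ``long_threshold`` net bases are classed "long", the rest "short".
    """
    L = len(genome)
    blockers = table.of_type("CDS", "rRNA")
    if not blockers:
        raise ValidationError("annotation table has no CDS/rRNA features")
    covered = np.zeros(L, dtype=bool)
    for f in blockers:
        if f.end >= f.start:
            covered[f.start - 1 : f.end] = True
        else:
            covered[f.start - 1 :] = True
            covered[: f.end] = True
    if covered.all():
        return []

    # maximal free runs, computed by rotating to a covered base
    first_cov = int(np.argmax(covered))
    rot = np.roll(~covered, -first_cov)
    regions = []
    i = 0
    n = L
    while i < n:
        if rot[i]:
            j = i
            while j < n and rot[j]:
                j += 1
            s = (i + first_cov) % L + 1
            e = (j - 1 + first_cov) % L + 1
            regions.append((s, e))
            i = j
        else:
            i += 1

    def upstream_gene(pos: int) -> str:
        best, best_d = "", None
        for f in blockers:
            d = (pos - f.end - 1) % L
            if best_d is None or d < best_d:
                best, best_d = f.gene, d
        return best

    def downstream_gene(pos: int) -> str:
        best, best_d = "", None
        for f in blockers:
            d = (f.start - pos - 1) % L
            if best_d is None or d < best_d:
                best, best_d = f.gene, d
        return best

    out = []
    for s, e in sorted(regions):
        span = circular_length(s, e, L)
        inside = []
        trna_bases = 0
        for f in table.of_type("tRNA"):
            off = (f.start - s) % L
            if off + f.length(L) <= span:  # fully inside the free interval
                inside.append(f.gene)
                trna_bases += f.length(L)
        length = span if include_trna_length else span - trna_bases
        out.append(NoncodingRegion(
            start=s, end=e, length=length, span=span,
            interrupting_features=tuple(inside),
            flanking_genes=(upstream_gene(s), downstream_gene(e)),
            klass="long" if length >= long_threshold else "short",
        ))
    return out


def survey_gene_lengths(entries: list, gene: str) -> dict:
    """Summarise a protein-coding gene's length (aa) across a species panel.

    ``entries`` is a list of (species, protein) pairs or (species, length)
    pairs.  Returns n/min/max/mean (mean rounded to the nearest integer)
    plus the per-species lengths.  Species lacking the gene should simply
    be absent from ``entries``.
    """
    per_species = {}
    for species, value in entries:
        per_species[species] = len(value) if isinstance(value, str) else int(value)
    if not per_species:
        raise ValidationError(f"no species provides gene {gene!r}")
    lengths = list(per_species.values())
    return {
        "gene": gene,
        "n": len(lengths),
        "min": min(lengths),
        "max": max(lengths),
        "mean": round(sum(lengths) / len(lengths)),
        "per_species": per_species,
    }


def _region_bounds(region) -> tuple[int, int]:
    return region.start, region.end


def discover_candidate_orfs(genome: Genome, table: AnnotationTable,
                            regions: list, codon_table: CodonTable = TABLE_9,
                            min_len: int = 25) -> list[CandidateOrf]:
    """Find start-anchored ORFs fully inside noncoding/transcribed regions.

    Unlike the genome-wide stop-to-stop scan, candidates here are anchored
    at an initiator codon: with no homology to define an upstream extent,
    the most upstream in-frame start of each (frame, stop) pair opens the
    ORF, and the remaining in-frame starts are kept as alternatives.  The
    ORF and its stop codon must lie entirely within the region and reach
    ``min_len`` residues (stop excluded).
    """
    L = len(genome)
    out = []
    for region in regions:
        rs, re_ = _region_bounds(region)
        span = circular_length(rs, re_, L)
        seq = genome.fetch(rs, re_)
        found: dict[tuple[int, int], dict] = {}  # (frame, stop_off) -> info
        for off in range(0, span - 2):
            codon = seq[off : off + 3]
            if codon not in codon_table.start_codons:
                continue
            # extend to the first in-frame stop inside the region
            stop_off = None
            for j in range(off, span - 2, 3):
                if codon_table.is_stop(seq[j : j + 3]):
                    stop_off = j
                    break
            if stop_off is None:
                continue
            n_aa = (stop_off - off) // 3
            if n_aa < min_len:
                continue
            key = (off % 3, stop_off)
            entry = found.get(key)
            if entry is None:
                # offsets ascend, so the first hit is the most upstream start
                found[key] = {"off": off, "stop": stop_off, "starts": [off]}
            else:
                entry["starts"].append(off)

        for (frame, stop_off), info in sorted(found.items(),
                                              key=lambda kv: kv[1]["off"]):
            off = info["off"]
            g_start = (rs - 1 + off) % L + 1
            g_end = (rs - 1 + stop_off - 1) % L + 1
            nt = seq[off:stop_off]
            protein = translate(nt, codon_table, as_initiator=True)
            cands = [((rs - 1 + o) % L + 1, seq[o : o + 3])
                     for o in sorted(set(info["starts"]))]
            orf = Orf(genome_id=genome.id, frame=(g_start - 1) % 3,
                      start=g_start, end=g_end, protein=protein,
                      candidate_starts=cands, chosen_start=g_start)
            blockers = table.of_type("CDS", "rRNA", "tRNA")
            after, dist = "", None
            for f in blockers:
                d = (g_start - f.end - 1) % L
                if dist is None or d < dist:
                    after, dist = f.gene, d
            tm = hydropathy_tm(protein) if len(protein) >= 19 else []
            sig = signal_like_nterm(protein) if len(protein) >= 15 else False
            out.append(CandidateOrf(
                orf=orf, after_gene=after,
                distance_from_after_gene=int(dist if dist is not None else 0),
                tm_segments=tm, has_signal_like_nterm=sig,
            ))
    return out


def hydropathy_tm(protein: str, window: int = 19,
                  threshold: float = 1.6) -> list:
    """Kyte-Doolittle transmembrane-segment scan.

    Every window of ``window`` residues whose mean hydropathy reaches
    ``threshold`` marks its span; overlapping spans are merged.  Segments
    are reported as (start_aa, end_aa, mean_hydropathy) in 1-based residue
    coordinates.  Proteins shorter than the window yield no segments.
    """
    n = len(protein)
    if n < window:
        warnings.warn(f"protein of {n} aa shorter than window {window}",
                      stacklevel=2)
        return []
    kd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein.upper()])
    csum = np.concatenate([[0.0], np.cumsum(kd)])
    means = (csum[window:] - csum[:-window]) / window  # window starting at i
    # tolerance keeps exact-threshold windows in despite summation order
    hits = np.flatnonzero(means >= threshold - 1e-9)
    if hits.size == 0:
        return []
    segments = []
    seg_start = int(hits[0])
    prev = int(hits[0])
    for h in hits[1:]:
        h = int(h)
        if h - prev <= window:  # windows overlap or abut -> same segment
            prev = h
        else:
            segments.append((seg_start, prev))
            seg_start = prev = h
    segments.append((seg_start, prev))
    out = []
    for s, e in segments:
        lo, hi = s + 1, e + window  # 1-based inclusive residue span
        mean = float(kd[lo - 1 : hi].mean())
        out.append((lo, hi, mean))
    return out


def signal_like_nterm(protein: str, stretch: int = 7,
                      threshold: float = 1.6) -> bool:
    """Signal-peptide-like N-terminus heuristic.

    True when (1) a positively charged residue (K/R) occurs within the
    first five residues, and (2) somewhere within the first thirty
    residues, starting after that charged residue, a stretch of
    ``stretch`` consecutive residues has mean Kyte-Doolittle hydropathy of
    at least ``threshold``.  This mimics the classic n-region/h-region
    layout of signal anchors; it is a heuristic, not a trained predictor.
    """
    if len(protein) < 15:
        raise ValidationError("signal_like_nterm needs >= 15 residues")
    head = protein[:30].upper()
    charged = [i for i, c in enumerate(head[:5]) if c in "KR"]
    if not charged:
        return False
    first_kr = charged[0]
    kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in head]
    for i in range(first_kr + 1, len(head) - stretch + 1):
        if sum(kd[i : i + stretch]) / stretch >= threshold:
            return True
    return False
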