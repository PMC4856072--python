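"""Circular gene-order canonicalization and comparison.

Triclad mitochondrial genomes keep all genes on one strand, so gene orders
are unsigned circular sequences of labels.  Differences between species are
almost entirely tRNA repositionings; the "tRNA difference" between two
genomes is operationalized here as the size of the smallest set of tRNA
labels whose deletion from both circular orders makes them identical up to
rotation.  Constructed relocations of one tRNA, two tRNAs, or a block of
three therefore score 1, 2, and 3 respectively — matching how such
rearrangements are counted by eye on gene-order schematics.

Conserved blocks (e.g. the cytb-nad4L-nad4 cartridge shared across
flatworms) are maximal runs of genes that are contiguous and in the same
relative order in every genome of a panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .core_io import AnnotationTable, ValidationError

__all__ = ["GeneOrder", "OrderComparison", "order_from_annotations",
           "trna_difference", "conserved_blocks"]


@dataclass
class GeneOrder:
    """Rotation-invariant circular list of (label, class) pairs.

    ``class`` is "tRNA" or "major" (protein-coding genes and rRNAs).
    The canonical form starts at the anchor gene (default cox1).
    """

    species: str
    order: list  # [(label, klass), ...] already rotated to the anchor
    anchor: str = "cox1"

    def labels(self) -> list[str]:
        return [lab for lab, _ in self.order]

    def trnas(self) -> list[str]:
        return [lab for lab, k in self.order if k == "tRNA"]

    def majors(self) -> list[str]:
        return [lab for lab, k in self.order if k == "major"]

    def __len__(self) -> int:
        return len(self.order)


@dataclass
class OrderComparison:
    species_pair: tuple
    trna_difference: int
    relocated_trnas: set = field(default_factory=set)
    major_gene_identical: bool = True
    unresolved: bool = False


def _rotate_to(items: list, anchor_label: str) -> list:
    labels = [lab for lab, _ in items]
    if anchor_label not in labels:
        raise ValidationError(f"anchor gene {anchor_label!r} absent from order")
    i = labels.index(anchor_label)
    return items[i:] + items[:i]


def _suffix_duplicates(items: list) -> list:
    seen: dict[str, int] = {}
    out = []
    for lab, k in items:
        n = seen.get(lab, 0) + 1
        seen[lab] = n
        out.append((lab if n == 1 else f"{lab}-{n}", k))
    return out


def order_from_annotations(table: AnnotationTable,
                           anchor: str = "cox1") -> GeneOrder:
    """Project an annotation table onto its circular gene order.

    ncRNA and ORF features are excluded; tRNAs keep their class, everything
    else is "major".  Duplicate labels get positional suffixes (-2, -3 ...)
    and wrap-around features are placed by their start coordinate.
    """
    feats = [f for f in table.features if f.type in ("CDS", "tRNA", "rRNA")]
    feats.sort(key=lambda f: f.start)
    items = [(f.gene, "tRNA" if f.type == "tRNA" else "major") for f in feats]
    items = _suffix_duplicates(items)
    items = _rotate_to(items, anchor)
    return GeneOrder(species=table.genome_id, order=items, anchor=anchor)


def _canonical_rotation(labels: tuple) -> tuple:
    """Lexicographically least rotation — a rotation-invariant signature."""
    if not labels:
        return labels
    best = labels
    for i in range(1, len(labels)):
        rot = labels[i:] + labels[:i]
        if rot < best:
            best = rot
    return best


def _equal_up_to_rotation(a: tuple, b: tuple) -> bool:
    return len(a) == len(b) and _canonical_rotation(a) == _canonical_rotation(b)


def _delete(labels: list, drop: set) -> tuple:
    return tuple(lab for lab in labels if lab not in drop)


def trna_difference(a: GeneOrder, b: GeneOrder, max_k: int = 4,
                    frozen_labels: set | None = None) -> OrderComparison:
    """Minimal tRNA deletion set that reconciles two circular orders.

    Searches all subsets of tRNA labels of size 0..``max_k``; the smallest
    subset whose removal from *both* orders leaves the same circular
    sequence is reported.  If none exists within ``max_k``, the comparison
    is flagged unresolved and the difference reported as ``max_k + 1`` (a
    lower bound).  ``frozen_labels`` excludes labels (e.g. duplicated tRNAs
    of uncertain provenance) from the candidate set.
    """
    la, lb = a.labels(), b.labels()
    majors_equal = _equal_up_to_rotation(tuple(a.majors()), tuple(b.majors()))

    shared_trnas = sorted((set(a.trnas()) | set(b.trnas()))
                          - (frozen_labels or set()))

    for k in range(0, max_k + 1):
        hits = []
        for sub in combinations(shared_trnas, k):
            drop = set(sub)
            if _equal_up_to_rotation(_delete(la, drop), _delete(lb, drop)):
                hits.append(drop)
        if hits:
            best = min(hits, key=sorted)
            return OrderComparison(
                species_pair=(a.species, b.species), trna_difference=k,
                relocated_trnas=best, major_gene_identical=majors_equal,
            )
    return OrderComparison(
        species_pair=(a.species, b.species), trna_difference=max_k + 1,
        relocated_trnas=set(), major_gene_identical=majors_equal,
        unresolved=True,
    )


def conserved_blocks(orders: list, min_block: int = 2) -> list:
    """Maximal gene runs contiguous and co-ordered in every circular order.

    Only labels present in all orders participate.  Adjacencies of the
    first order (restricted to the shared label set) are intersected with
    those of every other order; maximal runs of conserved adjacencies of
    at least ``min_block`` genes are returned as label lists.  When the
    entire order is shared, the single block is the whole circle.
    """
    if len(orders) < 2:
        raise ValidationError("need at least two gene orders")
    shared = set(orders[0].labels())
    for o in orders[1:]:
        shared &= set(o.labels())
    if not shared:
        return []

    def adjacencies(o: GeneOrder) -> set:
        labs = [l for l in o.labels() if l in shared]
        return {(labs[i], labs[(i + 1) % len(labs)]) for i in range(len(labs))}

    common = adjacencies(orders[0])
    for o in orders[1:]:
        common &= adjacencies(o)

    ref = [l for l in orders[0].labels() if l in shared]
    n = len(ref)
    if n == 0:
        return []
    conserved_edge = [
        (ref[i], ref[(i + 1) % n]) in common for i in range(n)
    ]
    if all(conserved_edge):
        return [list(ref)] if n >= min_block else []

    # walk runs of conserved adjacencies, starting after a broken edge
    start = (conserved_edge.index(False) + 1) % n
    blocks = []
    run = [ref[start]]
    for step in range(n):
        i = (start + step) % n
        if conserved_edge[i]:
            run.append(ref[(i + 1) % n])
        else:
            if len(run) >= min_block:
                blocks.append(run)
            run = [ref[(i + 1) % n]]
    # the final run ends on a broken edge by construction of `start`
    return blocks
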