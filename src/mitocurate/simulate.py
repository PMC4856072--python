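"""Synthetic circular mitochondrial genomes with planted ground truth.

The generator emulates the architecture of a triclad mitochondrial
chromosome: a single circular sequence of roughly 20 kb carrying 12
protein-coding genes, 2 rRNAs and 22 tRNAs, all on one strand, with
AT-rich intergenic gaps, a long terminal noncoding region, and (optionally)
planted long noncoding RNAs and per-gene coverage plateaus with sharp
boundaries.  Every structural fact about the output — start codon and
position of each gene, lncRNA intervals, coverage step positions, which
tRNAs were relocated between species — is recorded in a SyntheticTruth
object so that recovery by the analysis stages can be scored exactly.

Construction guarantees worth knowing:

* Each CDS is back-translated from a random amino-acid string using only
  non-stop codons of the flatworm code, so its interior is stop-free by
  construction; an in-frame TAA is written immediately upstream of the
  planted start codon so the stop-to-stop ORF opens exactly at the start.
* Ortholog panels share species 1's proteins mutated by point
  substitutions only (no indels) with the planted start codon preserved.
* The cob-nad4L-nad4 cartridge is kept contiguous (no tRNA insertions) in
  every species, mirroring its conservation across flatworms.
* tRNA relocations move a tRNA into a different inter-gene slot, so the
  minimal tRNA deletion set between species 1 and a derived species is
  exactly the relocated set.
* All randomness flows from one integer seed; identical configs give
  byte-identical genomes, tables and coverage tracks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import (AnnotationTable, GeneAnnotation, Genome,
                      write_annotation_table, write_fasta)
from .orf_engine import TABLE_9, CodonTable, translate
from .transcription import CoverageTrack, write_coverage_tsv

__all__ = ["SimulationConfig", "SyntheticTruth", "PackingError",
           "simulate_genome", "simulate_panel", "simulate_coverage",
           "write_simulation"]

# canonical gene roster with realistic triclad protein lengths (aa)
_GENE_LENGTHS = [
    ("cox1", 630), ("cox2", 220), ("cox3", 255), ("cob", 360),
    ("nad1", 290), ("nad2", 320), ("nad3", 115), ("nad4", 430),
    ("nad4L", 95), ("nad5", 540), ("nad6", 150), ("atp6", 220),
]
_RRNA_LENGTHS = [("rrnS", 700), ("rrnL", 950)]
_TRNA_LABELS = [
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
]
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_GAP_NT = np.array(list("ATGC"))
_GAP_P = np.array([0.35, 0.35, 0.15, 0.15])  # AT-rich intergenic sequence


class PackingError(ValueError):
    """Features plus gaps do not fit in the configured genome length."""


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20_000
    n_protein_genes: int = 12
    n_trnas: int = 22
    n_rrnas: int = 2
    gap_length_distribution: tuple = (50, 150)
    start_codon_mix: dict = field(
        default_factory=lambda: {"ATG": 0.4, "GTG": 0.1, "TTG": 0.5})
    planted_lncrnas: list = field(default_factory=lambda: [(1000, 200.0)])
    dropoff_at_boundaries: bool = True
    background_depth: float = 0.0
    antisense_rrna_rate: float = 0.05
    n_species: int = 4
    substitution_rate: float = 0.15
    trna_relocations: int = 1

    def __post_init__(self):
        total = sum(self.start_codon_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("start_codon_mix probabilities must sum to 1")
        if self.n_protein_genes > len(_GENE_LENGTHS):
            raise ValueError(f"at most {len(_GENE_LENGTHS)} protein genes")
        if self.n_trnas > len(_TRNA_LABELS):
            raise ValueError(f"at most {len(_TRNA_LABELS)} tRNAs")
        if self.n_rrnas > len(_RRNA_LENGTHS):
            raise ValueError(f"at most {len(_RRNA_LENGTHS)} rRNAs")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed per species."""

    species: list
    genomes: dict          # species -> Genome
    tables: dict           # species -> AnnotationTable
    proteins: dict         # species -> {gene: protein}
    true_starts: dict      # (species, gene) -> (position, codon)
    true_lncrnas: dict     # species -> [(start, end, depth)]
    true_dropoffs: dict    # species -> [(position, direction)]
    relocated_trnas: set
    config: SimulationConfig

    def reference_proteins(self) -> dict:
        return dict(self.proteins[self.species[0]])


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gap_seq(rng, n: int) -> str:
    return "".join(rng.choice(_GAP_NT, size=n, p=_GAP_P)) if n else ""


def _random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def _mutate_protein(rng, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # never touch the initiator residue
        if rng.random() < rate:
            alt = [a for a in _AA20 if a != out[i]]
            out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def _back_translate(rng, protein: str, start_codon: str,
                    table: CodonTable = TABLE_9) -> str:
    """Codon sequence whose plain translation is ``protein`` with its first
    codon forced to ``start_codon`` (the planted initiator)."""
    codons = [start_codon]
    for aa in protein[1:]:
        options = table.synonymous_codons(aa)
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _build_units(rng, config: SimulationConfig):
    """Shuffled gene units; the cob-nad4L-nad4 cartridge stays one unit."""
    genes = [g for g, _ in _GENE_LENGTHS[: config.n_protein_genes]]
    cartridge = [g for g in ("cob", "nad4L", "nad4") if g in genes]
    units = [[g] for g in genes if g not in cartridge]
    if cartridge:
        units.append(cartridge)
    for r, _ in _RRNA_LENGTHS[: config.n_rrnas]:
        units.append([r])
    units = [units[i] for i in rng.permutation(len(units))]
    return units


def _assign_trna_slots(rng, config: SimulationConfig, n_slots: int) -> dict:
    labels = _TRNA_LABELS[: config.n_trnas]
    return {t: int(rng.integers(n_slots)) for t in labels}


def _full_order(units, trna_slots) -> list:
    """Interleave units and tRNAs into one circular feature order."""
    order = []
    for i, unit in enumerate(units):
        for g in unit:
            order.append((g, "major"))
        for t in sorted(trna_slots):
            if trna_slots[t] == i:
                order.append((t, "tRNA"))
    return order


def _assemble_species(rng, config, order, proteins, start_codons,
                      rrna_len, species):
    """Lay one species' features onto a fresh sequence; returns everything
    coordinate-bearing for that species."""
    gmin, gmax = config.gap_length_distribution
    parts: list[str] = []
    cursor = 0
    features: list[GeneAnnotation] = []
    starts: dict[str, tuple[int, str]] = {}

    for label, klass in order:
        gap = int(rng.integers(gmin, gmax + 1))
        parts.append(_gap_seq(rng, gap))
        cursor += gap
        if klass == "major" and label in proteins:
            parts.append("TAA")  # in-frame bound: the ORF opens at the start
            cursor += 3
            codon = start_codons[label]
            nt = _back_translate(rng, proteins[label], codon)
            stop = "TAA" if rng.random() < 0.5 else "TAG"
            start = cursor + 1
            parts.append(nt + stop)
            cursor += len(nt) + 3
            features.append(GeneAnnotation(gene=label, type="CDS",
                                           start=start, end=cursor,
                                           start_codon=codon))
            starts[label] = (start, codon)
        elif klass == "major":  # rRNA
            n = rrna_len[label]
            start = cursor + 1
            parts.append("".join(rng.choice(_GAP_NT, size=n)))
            cursor += n
            features.append(GeneAnnotation(gene=label, type="rRNA",
                                           start=start, end=cursor))
        else:  # tRNA
            n = int(rng.integers(60, 71))
            start = cursor + 1
            parts.append(_gap_seq(rng, n))
            cursor += n
            features.append(GeneAnnotation(gene=label, type="tRNA",
                                           start=start, end=cursor))

    tail = config.genome_length - cursor
    lnc_lengths = [int(n) for n, _ in config.planted_lncrnas]
    needed = sum(lnc_lengths) + 100 * (len(lnc_lengths) + 1)
    if tail < max(needed, 1):
        raise PackingError(
            f"features occupy {cursor} bp; tail of {tail} bp cannot hold "
            f"{len(lnc_lengths)} planted lncRNAs (+margins) in a "
            f"{config.genome_length} bp genome"
        )
    lncrnas = []
    off = cursor + 100
    for n, depth in config.planted_lncrnas:
        lncrnas.append((off + 1, off + int(n), float(depth)))
        off += int(n) + 100
    parts.append(_gap_seq(rng, tail))
    sequence = "".join(parts)
    assert len(sequence) == config.genome_length

    genome = Genome(id=species, sequence=sequence, species=species)
    table = AnnotationTable(genome_id=species, features=features)
    table.validate_against(genome)

    L = config.genome_length
    dropoffs = []
    for f in features:
        if f.type in ("CDS", "rRNA"):
            dropoffs.append(((f.start - 2) % L + 1, "up"))
            dropoffs.append((f.end, "down"))
    for s, e, _ in lncrnas:
        dropoffs.append(((s - 2) % L + 1, "up"))
        dropoffs.append((e, "down"))

    return genome, table, starts, lncrnas, sorted(dropoffs)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig | None = None) -> SyntheticTruth:
    """One synthetic species with full planted truth (species id "sp1")."""
    config = config or SimulationConfig()
    cfg = SimulationConfig(**{**asdict(config), "n_species": 1})
    return simulate_panel(cfg)


def simulate_panel(config: SimulationConfig | None = None) -> SyntheticTruth:
    """A panel of ``n_species`` orthologous genomes derived from species 1.

    Species 2..n carry point-substituted proteins (rate
    ``substitution_rate`` per residue, initiator untouched) and
    ``trna_relocations`` tRNAs moved to different inter-gene slots.  Gap
    lengths, codon choices and tRNA sequences are redrawn per species, so
    coordinates differ even where the gene order does not.
    """
    config = config or SimulationConfig()
    if config.n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = _rng(config, 0)

    units = _build_units(rng, config)
    slots = _assign_trna_slots(rng, config, len(units))
    gene_lengths = dict(_GENE_LENGTHS[: config.n_protein_genes])
    rrna_len = dict(_RRNA_LENGTHS[: config.n_rrnas])

    codon_names = sorted(config.start_codon_mix)
    codon_p = np.array([config.start_codon_mix[c] for c in codon_names])
    start_codons = {
        g: codon_names[rng.choice(len(codon_names), p=codon_p)]
        for g in gene_lengths
    }
    base_proteins = {}
    for g, n in gene_lengths.items():
        aa0 = translate(start_codons[g], TABLE_9)  # M/V/L per planted codon
        base_proteins[g] = aa0 + _random_protein(rng, n - 1)

    # choose relocations once; applied to every derived species
    relocated: list[tuple[str, int]] = []
    if config.trna_relocations and config.n_species > 1:
        labels = sorted(slots)
        picks = rng.choice(len(labels), size=config.trna_relocations,
                           replace=False)
        for i in picks:
            t = labels[int(i)]
            new = int(rng.integers(len(units)))
            while new == slots[t]:
                new = int(rng.integers(len(units)))
            relocated.append((t, new))

    species_names = [f"sp{i + 1}" for i in range(config.n_species)]
    genomes, tables, proteins = {}, {}, {}
    true_starts, true_lncrnas, true_dropoffs = {}, {}, {}

    for si, sp in enumerate(species_names):
        sp_rng = _rng(config, 1 + si)
        if si == 0:
            sp_proteins = dict(base_proteins)
            sp_slots = dict(slots)
        else:
            sp_proteins = {g: _mutate_protein(sp_rng, p,
                                              config.substitution_rate)
                           for g, p in base_proteins.items()}
            sp_slots = dict(slots)
            for t, new in relocated:
                sp_slots[t] = new
        order = _full_order(units, sp_slots)
        genome, table, starts, lncrnas, dropoffs = _assemble_species(
            sp_rng, config, order, sp_proteins, start_codons, rrna_len, sp)
        genomes[sp] = genome
        tables[sp] = table
        proteins[sp] = sp_proteins
        for g, (pos, codon) in starts.items():
            true_starts[(sp, g)] = (pos, codon)
        true_lncrnas[sp] = lncrnas
        true_dropoffs[sp] = dropoffs

    return SyntheticTruth(
        species=species_names, genomes=genomes, tables=tables,
        proteins=proteins, true_starts=true_starts,
        true_lncrnas=true_lncrnas, true_dropoffs=true_dropoffs,
        relocated_trnas={t for t, _ in relocated}, config=config,
    )


def simulate_coverage(truth: SyntheticTruth, species: str | None = None,
                      ) -> CoverageTrack:
    """Stranded per-base coverage for one species of a SyntheticTruth.

    Each CDS/rRNA gets a plateau depth drawn log-uniformly from 10-2000x
    (sharp edges when ``dropoff_at_boundaries``, else 25 bp linear ramps);
    planted lncRNAs get their configured depths; everything else sits at
    ``background_depth``.  Per-base depths are Poisson draws around the
    expectation.  Antisense coverage is zero except inside rRNA loci,
    where it is Poisson(antisense_rrna_rate x sense expectation) — the
    non-polyA rRNA contamination signature.  tRNAs are left untranscribed
    (polyA selection does not capture them).
    """
    config = truth.config
    species = species or truth.species[0]
    si = truth.species.index(species)
    rng = _rng(config, 1001 + si)
    table = truth.tables[species]
    L = config.genome_length

    sense_exp = np.full(L, float(config.background_depth))
    rrna_mask = np.zeros(L, dtype=bool)
    for f in table.features:
        if f.type not in ("CDS", "rRNA"):
            continue
        depth = float(np.exp(rng.uniform(np.log(10.0), np.log(2000.0))))
        idx = np.arange(f.start - 1, f.start - 1 + f.length(L)) % L
        sense_exp[idx] = depth
        if not config.dropoff_at_boundaries:
            ramp = min(25, len(idx) // 4)
            for k in range(ramp):
                sense_exp[idx[k]] *= (k + 1) / (ramp + 1)
                sense_exp[idx[-1 - k]] *= (k + 1) / (ramp + 1)
        if f.type == "rRNA":
            rrna_mask[idx] = True
    for s, e, depth in truth.true_lncrnas[species]:
        sense_exp[s - 1 : e] = depth

    sense = rng.poisson(sense_exp).astype(float)
    anti_exp = np.where(rrna_mask,
                        config.antisense_rrna_rate * sense_exp, 0.0)
    antisense = rng.poisson(anti_exp).astype(float)
    return CoverageTrack(genome_id=species, sense=sense, antisense=antisense)


def write_simulation(truth: SyntheticTruth, outdir,
                     with_coverage: bool = True) -> None:
    """Write FASTA, annotation TSVs, coverage TSVs and a truth JSON."""
    import os
    os.makedirs(outdir, exist_ok=True)
    write_fasta([truth.genomes[sp] for sp in truth.species],
                os.path.join(outdir, "genomes.fa"))
    for sp in truth.species:
        write_annotation_table(truth.tables[sp],
                               os.path.join(outdir, f"{sp}.annotations.tsv"))
        if with_coverage:
            track = simulate_coverage(truth, sp)
            write_coverage_tsv(track, os.path.join(outdir, f"{sp}.coverage.tsv"))
    payload = {
        "species": truth.species,
        "true_starts": {f"{sp}:{g}": list(v)
                        for (sp, g), v in sorted(truth.true_starts.items())},
        "true_lncrnas": truth.true_lncrnas,
        "true_dropoffs": {sp: [[p, d] for p, d in v]
                          for sp, v in truth.true_dropoffs.items()},
        "relocated_trnas": sorted(truth.relocated_trnas),
        "config": asdict(truth.config),
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
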