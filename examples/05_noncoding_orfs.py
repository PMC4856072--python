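"""Catalogue noncoding regions and hunt for membrane-protein-like ORFs.

Catalogues the intergenic noncoding regions of a synthetic genome (net of
interrupting tRNAs), then searches a constructed nad2-downstream region
for a start-anchored ORF with transmembrane/signal-peptide-like
architecture — the signature used to flag a putative atp8.
"""

from mitocurate import (Genome, AnnotationTable, GeneAnnotation,
                        SimulationConfig, discover_candidate_orfs,
                        hydropathy_tm, noncoding_catalog, signal_like_nterm,
                        simulate_genome)

truth = simulate_genome(SimulationConfig(seed=3))
genome = truth.genomes["sp1"]
table = truth.tables["sp1"]

catalog = noncoding_catalog(table, genome, long_threshold=500)
longs = [r for r in catalog if r.klass == "long"]
print(f"{len(catalog)} noncoding regions, {len(longs)} long (>= 500 bp)")
for r in longs:
    print(f"  long NCR {r.start}-{r.end}: {r.length} bp net of "
          f"{len(r.interrupting_features)} interrupting tRNA(s) "
          f"{list(r.interrupting_features)}")

# A hand-built region after nad2 carrying an ORF with the atp8-like layout:
# positively charged N-terminus, hydrophobic core, one TM segment.
protein = "MKR" + "LIVLLIVALLIV" * 2 + "NQSTNQ" * 8
codons = {"M": "ATG", "K": "AAG", "R": "CGA", "L": "TTA", "I": "ATT",
          "V": "GTT", "A": "GCT", "N": "AAT", "Q": "CAA", "S": "TCA",
          "T": "ACT"}
orf_nt = "".join(codons[c] for c in protein) + "TAA"
seq = "C" * 900 + "C" * 150 + orf_nt + "C" * 250 + "C" * 600
g2 = Genome(id="demo", sequence=seq)
t2 = AnnotationTable(genome_id="demo", features=[
    GeneAnnotation("nad2", "CDS", 1, 900),
    GeneAnnotation("nad6", "CDS", len(seq) - 599, len(seq)),
])
t2.validate_against(g2)
regions = noncoding_catalog(t2, g2)
(cand,) = discover_candidate_orfs(g2, t2, regions)
print(f"candidate ORF after {cand.after_gene}: {len(cand.orf.protein)} aa, "
      f"{cand.distance_from_after_gene} bp downstream")
print(f"  TM segments (start_aa, end_aa, mean KD): {cand.tm_segments}")
print(f"  signal-peptide-like N-terminus: {cand.has_signal_like_nterm}")
assert hydropathy_tm(cand.orf.protein) == cand.tm_segments
assert signal_like_nterm(cand.orf.protein) == cand.has_signal_like_nterm
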