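# Methods

This note documents the models and procedures implemented in
`mitocurate`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the choices made where the
design was genuinely open.

## Coordinate model

All coordinates are 1-based inclusive on a circular chromosome; a feature
with `end < start` wraps the origin. Circular interval length is
`end − start + 1` when `end ≥ start`, else `L − start + 1 + end`. Every
interval is strictly sub-genomic (a feature never covers the whole
circle). Signed gaps between features are folded into `[−L/2, L/2)`, so a
small overlap across the origin reads as a small negative number rather
than a near-genome-length gap. BED/bedGraph I/O converts to 0-based
half-open at the boundary of the package and nowhere else; GFF3 output
splits wrapped features into two parts sharing an `ID`.

Only "+"-strand features are accepted. Single-strand transcription is a
modelling assumption, not an observation the package re-derives: genomes
whose annotation carries minus-strand features are outside its scope and
rejected at read time.

## Genetic code and ORF model

Translation uses the echinoderm/flatworm mitochondrial code (table 9:
AAA→N, AGA/AGG→S, TGA→W, stops TAA/TAG), shipped as a literal 64-codon
map and cross-checked in the tests against Biopython's table 9. The
initiator set is `{ATG, GTG, TTG}` ("9+TTG"): TTG is included because
cross-species homology repeatedly extends upstream of any in-frame ATG in
these genomes, and GTG so that the selection stage can meaningfully
reject it. Any initiator translates to Met when used as a first codon.

ORFs are **stop-to-stop** maximal segments, not start-anchored ones,
because start choice is exactly what the downstream refinement stage
decides; anchoring at starts would hide the upstream homology the method
relies on. Scanning conceptually doubles the sequence so segments may
wrap the origin; segments are deduplicated by their circular start and
can never exceed one genome length. A frame with no stop at all yields a
single capped segment flagged `no_stop`. Abbreviated stop codons
(T/TA completed by polyadenylation) are not modelled; a segment ends at
the next full stop. The default length floor is 80 aa.

## Start refinement

1. **Grouping.** Each species' ORFs are scored against each reference
   protein by exact Smith–Waterman (BLOSUM62, gap open 11 / extend 1 —
   the classic protein-search parameters; residues outside the matrix
   alphabet are mapped to X). An ORF joins its best-scoring gene, one ORF
   per species per gene, with a raw-score floor of 50. A raw score
   replaces an E-value deliberately: the panel is a handful of sequences,
   so database-size statistics add nothing. The alignment engine is
   Biopython's `PairwiseAligner`; the tests verify its scores against an
   independent full-matrix Gotoh implementation.
2. **Multiple alignment.** Center-star progressive alignment: the center
   is the member with the maximal summed pairwise score; others are
   globally aligned to it with free end gaps; gaps are merged "once a
   gap, always a gap". This is deterministic and entirely adequate for
   ≤ 10 closely related sequences; it is *not* a general-purpose MSA.
   Column occupancy is the fraction of non-gap rows per column.
3. **Selection.** Every in-frame initiator candidate `c` scores
   `#{columns with occupancy ≥ 0.5 at or downstream of c's column}
   − 1.0 × overlap(c, upstream feature in bases)`. The form encodes two
   pressures: the chosen start should open the conserved block (columns
   upstream of the start contribute nothing), and it should not run the
   gene deep into its neighbour. Ties prefer ATG over GTG over TTG, then
   the most upstream position. Both constants (occupancy threshold 0.5,
   overlap penalty 1/base) are exposed; they are the package's own
   formalization of an otherwise verbal curation rule, and the planted-
   truth experiments show the selection is insensitive to them in the
   regime the generator produces (gapless alignments, overlap-free true
   starts). Intergenic gap length is reported per call but not scored:
   overlapping genes are a real feature of these genomes (the
   cytb–nad4L–nad4 cartridge), so distance alone must not veto a start.

## Transcription evidence

* **Strand test.** `sum(sense) / (sum(sense)+sum(antisense))`, by default
  over positions outside rRNA features, because polyA selection leaves
  non-polyA rRNA fragments that align antisense without being evidence of
  antisense transcription. Zero coverage returns NaN: no data supports
  neither 0 nor 1.
* **Region calling.** Positions with sense depth ≥ `min_mean_depth / 2`
  form runs; runs separated by fewer than 50 uncovered bases merge;
  surviving regions need ≥ 100 bp (the conventional lncRNA length floor)
  and mean depth ≥ `min_mean_depth`. A region is "intergenic" when less
  than 10% of it overlaps any annotated feature. The floor/merge/filter
  scheme is this package's formalization — the depths reported for real
  genomes are approximate and no published algorithm exists to copy.
* **Drop-offs.** Every circular boundary scores
  `log2((mean_left + 1)/(mean_right + 1))` over 50-base flanks; the +1
  pseudocount keeps zero-coverage flanks finite. Local extrema with
  |score| ≥ 2 are kept and greedily thinned (strongest first) to a
  100-base minimum separation **per direction**: a cleavage site produces
  one down- and one up-step that may legitimately sit a short gap apart,
  so opposite signs never suppress each other. Sites are invariant under
  uniform depth scaling up to the pseudocount (tested at ×10).

## Gene order

Orders are unsigned circular label sequences (all genes on one strand, so
orientation carries no information), rotated to a canonical anchor
(cox1). The "tRNA difference" between two genomes is the size of the
smallest set of tRNA labels whose deletion from both orders makes them
identical up to rotation, found by exhaustive subset search (size ≤ 4 by
default, a few thousand candidate subsets at mitochondrial scale). The
measure is symmetric and zero exactly on rotation-equal orders; it is not
claimed to satisfy the triangle inequality. Duplicate labels receive
positional suffixes; they can be frozen out of the candidate set when
their provenance (duplication vs annotation error) is unclear. Conserved
blocks are maximal runs of shared labels contiguous and co-ordered in
every input order, computed by intersecting circular adjacencies.

## Noncoding regions and candidate ORFs

A noncoding region is a maximal circular interval free of CDS and rRNA
features. tRNAs inside it are recorded as interruptions and excluded from
the reported length by default (a span-inclusive alternative is a flag):
a multi-kilobase region "interrupted by a single tRNA" is treated as one
region, and the net convention makes noncoding + genic + tRNA bases tile
the genome exactly — an identity the tests audit. Regions ≥ 500 bp are
classed "long"; the threshold separates the multi-hundred-bp spacers from
the kilobase-scale regions seen in real genomes and is configurable.

Candidate ORFs inside noncoding/transcribed regions are **start-anchored**
(most upstream in-frame initiator per stop), unlike the genome-wide scan,
because no homology exists to define their upstream extent. Both ORF and
stop must lie inside the region; the default floor is 25 aa, small enough
for an atp8-sized product. Membrane architecture uses the Kyte–Doolittle
scale with the standard transmembrane constants (window 19, cutoff 1.6):
every window at/above cutoff marks its span, overlapping spans merge. The
signal-peptide-like call is a rule-based heuristic — a K/R in the first
five residues followed, within the first thirty, by a ≥ 7-residue stretch
of windowed hydropathy ≥ 1.6 — mimicking the n-region/h-region layout of
signal anchors. Both are explicit heuristics and labelled as such; they
make no claim of equivalence to trained predictors, and a candidate is
never *functionally* assigned as atp8 on this evidence alone.

## Synthetic data

The generator emulates the architecture these analyses were designed for:
a 20 kb circle; 12 protein genes with realistic lengths (95–630 aa,
*cox1* at 630 aa so the extended-gene survey has its signature case);
2 rRNAs (700/950 bp); 22 tRNAs of 60–70 bp; AT-rich intergenic gaps of
50–150 bp; a terminal multi-kilobase noncoding region holding the planted
lncRNAs (default: one of 1,000 bp at 200×); start codons drawn
ATG 0.4 / GTG 0.1 / TTG 0.5, reflecting how common the noncanonical
initiator is in these genomes; the cob–nad4L–nad4 cartridge kept
contiguous in every species.

Construction details that make truth exactly recoverable:

* Proteins are random amino-acid strings back-translated with uniform
  synonymous-codon choice, so interiors are stop-free by construction;
  an in-frame TAA is written immediately upstream of each planted start,
  so the stop-to-stop ORF opens exactly at the start and the candidate
  list begins with the true codon.
* Ortholog panels apply point substitutions only (initiator residue
  untouched); there is no indel evolution, so homolog alignments are
  gapless and column occupancy is exactly 1. Passing recovery tests
  therefore shows the selection rule ranks candidates correctly under
  substitution noise — not that the aligner handles indel-rich or
  truncated orthologs.
* Relocated tRNAs always move to a *different* inter-gene slot, which
  makes the minimal deletion set provably equal to the relocated set.
* Coverage: per-gene plateau depths log-uniform on 10–2000× with sharp
  edges; tRNAs stay at background (polyA selection does not capture
  them); background defaults to 0× (un-transcribed DNA contributes no
  polyA reads); per-base depths are Poisson draws; antisense depth is
  Poisson(rate × sense) inside rRNAs only. Poisson is the simplest depth
  model; real tracks show overdispersion, mappability structure and
  soft transcript ends that this generator deliberately omits, so
  boundary-localization results here are an upper bound on real-data
  performance.

All randomness flows from one integer seed through named substreams;
identical configs give byte-identical genomes, tables and tracks.

## Problem sizes and numerics

Default experiment sizes — 4-species panels, 20 kb genomes, 20 seeds for
recovery experiments, 100–1,000 random instances for oracle-equivalence
checks — keep the full test suite under a minute on one core while
leaving the brute-force oracles exact rather than sampled. Window means
in the hydropathy scan are computed by cumulative sums; a 1e-9 tolerance
keeps windows that sit exactly at the cutoff from flipping with summation
order. Degenerate inputs are defined, not special-cased: zero-coverage
strand fractions are NaN, stop-free frames are capped and flagged,
proteins shorter than the hydropathy window yield no segments with a
warning, and unalignable single-member homolog groups are flagged rather
than dropped silently.

## Known limitations

* Abbreviated stop codons and polycistronic transcript processing are not
  modelled.
* The center-star aligner is not suitable for distant or indel-rich
  homologs; swap in a full MSA tool for such panels.
* The tRNA-difference search is exact only up to `max_k` (default 4);
  beyond that it reports a lower bound flagged `unresolved`.
* The signal-peptide heuristic is a stand-in with no claim of equivalence
  to trained predictors.
* Non-directional libraries carry no strand information; represent them
  with an all-zero antisense vector and treat the strand fraction as
  not applicable.
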