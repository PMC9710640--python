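# Methods

## The question the package answers

Metataxonomic surveys identify bacteria from amplicons of the 16S rRNA
gene, usually the V3V4 hypervariable region (~460 nt) or the
near-full-length V1V9 region (~1.5 kb). Treating an exact amplicon
sequence (an ASV, dereplicated at 100% identity) as a proxy for a species
assumes two things that frequently fail: that every genome yields a single
amplicon sequence, and that no two species yield the same one. Bacterial
genomes carry 1–15 rrn operons whose 16S copies may differ (allele
multiplicity), and identical alleles recur across species of a genus
(species overlap). `ribresolve` quantifies both failure modes for a set of
genomes: it extracts the 16S genes, amplifies them in silico, dereplicates
the products into alleles, and reports which species the chosen amplicon
can and cannot distinguish.

## In-silico PCR model

A primer site is an alignment of the IUPAC-degenerate primer to the
template that is gapless except for up to `max_insertion` extra template
bases inside the primer footprint (gaps in the primer) and up to
`max_deletion` primer positions aligned to a template gap. A non-gap
column is a mismatch iff the IUPAC expansions of primer and template
characters are disjoint (template ambiguity codes therefore match
permissively, by intersection). Defaults: `max_mismatch=1`,
`max_insertion=1`, `max_deletion=0` — the common tolerance for 16S primer
screening. 3'-anchoring is deliberately **not** enforced: a mismatch at
the primer 3' terminus counts as one mismatch like any other, which is a
known divergence from wet-lab PCR chemistry and is the main reason
in-silico products can be slightly optimistic.

Overlapping candidate alignments describe one binding locus; exactly one
site is reported per locus: fewest total edits, then leftmost start, then
shortest footprint, then fewest deletions, then fewest insertions. The
last two levels only matter when `max_deletion > 0` (an insertion plus a
deletion can reproduce another placement's footprint); they make the
output a total order and hence byte-reproducible.

The production matcher enumerates gap placements (there are O(L·(ins+del))
of them at default budgets for a primer of length L) and evaluates each
placement against all template offsets at once with vectorized
incompatibility profiles. An independent oracle (`oracle_find_sites`)
enumerates every start position and placement naively in pure Python;
matcher and oracle are required to return identical site lists on random
instances — that equivalence is part of the acceptance suite.

`amplify` scans both strands: each forward site pairs with the nearest
downstream reverse-complemented reverse-primer site whose product length
falls in `[min_len, max_len]` (defaults [50, 3000]; the window prevents
genome-scale products when whole contigs are scanned). One product per
forward site, no nested multi-products. Products on the "-" strand are
reported reverse-complemented, so every amplicon begins with the forward
primer footprint. Primer footprints are included in the product by default
(as a sequencer would see them) with a `--trim-primers` option; the length
window always refers to the untrimmed product so trimming never changes
which loci amplify.

## Gene extraction

Annotations win over anchoring: if a GFF3 file is supplied for a genome,
16S genes are taken from features of type `rRNA` whose `Name` or
`product` attribute contains "16S" (case-insensitive substring, tolerant
of NCBI vs annotation-tool spellings); minus-strand features are
reverse-complemented into gene orientation. Without an annotation, genes
are found by amplifying whole contigs with the V1V9 pair inside a
[1200, 2000] nt window — the plausible size range for a near-full-length
16S gene, excluding run-on products across neighbouring operons.

Either route is followed by the length filter: keep genes at least
`min_fraction` (default 0.9) of a reference full length (default 1550 nt,
the canonical 16S size). The 1395 nt cutoff at these defaults is inclusive.
The reference length is configurable because annotation pipelines measure
"fraction of full length" against slightly different gene models.

Species labels come from a metadata TSV (`genome_id → organism name`)
when given, else from the FASTA description line. The organism parser
takes the first token as genus and the second as species epithet, mapping
placeholders ("sp.", "sp", "bacterium") and missing epithets to the
`unclassified` sentinel.

## Dereplication and statistics

Amplicons are dereplicated at 100% identity: byte equality after
uppercase/U→T normalization. Sequences differing only in terminal length
are *different* alleles, and ambiguity codes are compared literally —
both choices are the strictest reading of the ASV concept and may be
stricter than pairwise-identity clustering tools, which can forgive
terminal gaps; the difference only matters for length-variant amplicons.
Allele ids are assigned size-major (ties by first appearance under the
pipeline's canonical amplicon sort by genome, contig, coordinate), so
numbering is deterministic and human-scannable.

From the genome × allele count matrix:

* **allele multiplicity** — % of genomes whose row has ≥2 non-zero
  entries;
* **species overlap** — % of *named* species that share at least one
  allele with a different named species. Genomes labelled `unclassified`
  never enter this percentage (numerator or denominator) but do appear in
  the genome confusion matrix and the pair listing; with no named species
  at all the percentage is reported as undefined rather than 0;
* **genome confusion matrix** — boolean genome × genome grid, true iff
  the two genomes share an allele (diagonal true);
* **indistinguishable groups** — connected components of the named
  species-sharing graph.

Percentages are kept at full precision internally and formatted half-up
to 2 decimals in reports. Heatmaps (optional) order rows and columns by
the leaf order of a Ward-linkage dendrogram on Euclidean distances
between raw count vectors — a display choice only; no statistic depends
on it.

## The synthetic genus generator

Real genome sets change with every database release, so correctness is
established on generated genera whose truth is known by construction. A
`GenusDesign` fixes: number of species and genomes per species, rrn copy
number range (default 4–7 per genome, within the biological 1–10), an
allele pool, within-genome variant count, a shared-allele plan (sets of
species forced to carry one identical allele), optional "twin" allele
pairs that are identical across the V3V4 window but differ outside it
(resolvable by V1V9 only), a count of unclassified ("sp.") genomes, a
background length (default 20 kb per genome) and a seed.

Pool alleles are 1550 nt: exact realizations of the V1V9 primer sites at
the termini and of the V3V4 sites at fixed internal offsets (340 and 800
for the footprint-inclusive window), with each allele receiving
`mutation_distance` (default 3) private substitutions inside the V3V4
window — distinct alleles therefore differ at ≥3 positions both in the
V3V4 amplicon and over the full gene, comfortably above the matching
tolerance. Genes are planted at ≥100 nt spacing on random uniform-ACGT
backgrounds, on random strands.

Truth would not survive a chance primer-like site in the random
background or across a gene/background junction, so every allele and
every assembled genome is screened with an independent near-match scanner
(gapless and single-interior-insertion alignments, mismatch budget 2 — a
strict superset of the default tolerance) and redrawn until the only
near-sites are the planted footprints. This makes truth recovery exact
for *any* seed, not just lucky ones. The screen covers the default
tolerance; truth guarantees do not extend to runs with
`max_mismatch + max_insertion > 2` or `max_deletion > 0` on synthetic
genomes.

All randomness flows from the design seed through two documented child
streams (stream 0: allele pool — base sequence, mutated positions,
substituted bases; stream 1: genomes in order — copy number, copy
distribution, placement gaps, strands, background bases, redraws), so
outputs are byte-reproducible.

What the generator does **not** emulate: rRNA secondary-structure-aware
evolution, chimeras, sequencing error (amplicons here are error-free by
design, matching the idealized ASV assumption), multi-contig assemblies
with genes split across contig boundaries, and non-uniform base
composition. Passing tests therefore demonstrate the correctness of the
pipeline's bookkeeping and matching semantics under idealized inputs, not
the biological representativeness of any particular genus.

## Problem sizes and numerical choices

The acceptance suite runs 1000 random matcher-vs-oracle instances
(templates ≤120 nt, primers 8–20 nt, tolerances (0,0,0), (1,0,0),
(1,1,0)) and 200 random genus designs cycling through the three
problematic scenarios — an allele shared across species, multi-variant
genomes, and variants individually shared — with 2–4 species, 1–2
genomes each, 2–7 rrn copies and up to 2 unclassified genomes per design.
These sizes exercise every code path (both extraction routes, both primer
pairs, both strands, all three scenario motifs) while each design remains
small enough to verify exhaustively.

Degenerate inputs are defined, not special-cased: zero amplicons is a
valid result (reports are written with empty data rows and a warning,
unless the run is configured to fail); a genome with zero amplicons keeps
an all-zero matrix row; a single-row matrix has the identity Ward order;
overlap with no named species is undefined, never 0.

## Known limitations

* No thermodynamic annealing model, primer-dimer prediction or
  3'-anchoring rule: site calling is purely combinatorial.
* Exact-equality dereplication can split length variants that
  pairwise-identity clustering would merge.
* The anchoring route only finds genes whose V1V9 sites survive within
  tolerance; genes with degenerate-primer sites damaged beyond the budget
  are invisible without an annotation.
* Organism parsing trusts binomial headers; curated metadata should be
  preferred where available.
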