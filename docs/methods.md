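# Methods

`endoreduce` analyzes sets of reduced endosymbiont genomes — the motivating
system is *Buchnera aphidicola*, the obligate maternally inherited symbiont
of aphids — against a free-living reference such as *Escherichia coli*.
This note documents the models, parameter choices and numerical rules, and
what the synthetic-data tests do and do not demonstrate about real data.

## The biological model

Obligate endosymbionts evolve clonally at small effective population size.
Under Muller's ratchet, relaxed selection lets deleterious substitutions
accumulate; because bacterial mutation is AT-biased, genes under weak
constraint drift toward low %GC while their protein sequences diverge from
the free-living homolog. Genome reduction proceeds almost entirely by
whole-gene loss with remarkable conservation of gene order, so positional
homology (synteny) is a reliable guide to gene families across genomes.
The package's central quantitative object is the per-gene pair
(%GC, percent protein identity to the reference homolog): the two axes are
driven by the same underlying loss of constraint and are therefore strongly
correlated, and their pooled means divide genes into four quadrants — Q3
(high GC, high identity: conserved), Q2 (low on both: deteriorating),
Q1 (high GC, low identity) and Q4 (low GC, high identity).

A note on quadrant labels: descriptions of "deteriorating" genes in parts
of the literature pair low identity with *low* %GC, which is this scheme's
Q2; the figure-caption convention adopted here fixes Q1 as high-GC/low-
identity. The classifier is explicit about the rule (ties go to the
"above" side) so results are reproducible either way, and thresholds
default to the pooled means of the analyzed gene set rather than any
hard-coded value — pooled means are dataset-specific. A flag can pin them.

## Homology

Every non-pseudo CDS is translated with the bacterial genetic code
(table 11) and aligned globally (Needleman–Wunsch, affine gaps) against
the reference proteome. Scoring is BLOSUM62 with gap open 11 / extend 1 in
the BLAST convention (a gap of length L costs 11 + L); the dynamic
programming engine is Biopython's `PairwiseAligner`, whose first-gap score
is shifted by one extension unit to realize that convention. Percent
identity divides identical columns by the alignment length after trimming
terminal-gap columns (internal gaps count); `shorter` and `longer`
denominators are available, and the array-construction steps use
`shorter` when judging fragments, since a half-length fragment is ~50%
identical to its own family under the alignment denominator.

Reciprocal best hits (RBH) pair each query with its best-scoring reference
gene (ties broken by identity, then id) and mark the pair reciprocal when
each is the other's best. Queries whose best raw score falls below
`min_score` (default 40) stay unassigned — the analogue of genes too
deteriorated for confident assignment. Duplicated genes yield exactly one
reciprocal copy; the other copy keeps the reference link without
reciprocity.

## The gene array

Rows are positional homolog families, columns genomes. Construction:

1. Seed rows from the first genome's gene order.
2. For each further (circular) genome, rotate its gene order to maximize
   ascending agreement with existing rows, then walk it gene by gene.
3. A gene anchors to a row sharing its reciprocal reference assignment or
   its gene name; candidate rows are searched nearest-first around the
   cursor so locally reversed (inverted) segments still land in their rows.
4. Genes with no matching row wait for their flanking anchor and are then
   either merged into the best-matching row in the flanking window
   (protein identity ≥ 30%, shorter-denominator — the "twilight zone"
   floor, configurable) or opened as new rows; a gene carrying its own
   family key opens an anchorable row, so families absent from the first
   genome still align across later ones.
5. A refinement pass folds single-occupant rows with no reference evidence
   into the better-matching adjacent row — severely eroded genes and split
   fragments in the first genome otherwise strand as orphan rows.

Pan/core counting compacts rows sharing a reference identity into one pan
unit (tandem duplicates and split fragments thereby count once); a unit is
core when every genome is represented across its rows. Split detection
looks for runs of genes, adjacent in one genome (at most one intervening
row), hitting the same reference gene with summed amino-acid length within
±15% of the reference; fragments without their own assignment inherit
their row's reference and have their relative length prorated from their
co-fragments. Two adjacent full-length copies sum to ~200% and are
classified as a duplication instead. Genes translated with an internal
stop are reported as split candidates independently.

Strand deviations compare each gene's strand with the row majority — or
with the reference orientation when supplied, which is both closer to
practice and necessary when only two genomes are compared or inversions
overlap. A run of ≥2 consecutive flipped rows whose local order is also
reversed is an inversion; isolated flips are direction changes. Syntenic
blocks scan rows with reference assignments and extend while consecutive
rows step through consecutive reference indices (+1 or −1 throughout);
rows without assignment are skipped by default so deteriorated genes do
not shatter blocks, and `size` counts assigned rows. Blocks do not wrap
the circular origin.

## Clustering, variants, expression

Gene-content clustering converts the presence/absence matrix to distances
d = 1 − Spearman ρ between genome columns and clusters them
agglomeratively (scipy linkage; average linkage by default, the common
default of classic clustering tools; complete and single available). The
dendrogram is serialized to newick with heights as node depths — the
topology is the scientific content.

Variant calling consumes per-site allele-count tables (or VCF with AD
fields): a site passes at depth ≥ 100, mean base quality ≥ Q20, and some
non-reference allele frequency ≥ 20%, all inclusive and configurable; one
record is emitted per passing alternate allele. Sites with frequency in
[0.20, 0.80] are "variable" — in a clonal, maternally transmitted symbiont
these intermediate frequencies are the signature of multiple co-resident
genotypes rather than sequencing noise, given the depth gate. Coding
effects re-translate the affected codon strand-aware (synonymous /
missense / stop-gained); indels of length not divisible by three are
frameshifts. The quality gate uses the producer-supplied per-site mean
base quality; the package deliberately consumes count tables rather than
BAMs to stay mapping-tool-agnostic.

Expression uses log2 CPM with a 0.5 pseudo-count against raw library
sizes (TMM-style factors can be supplied as external library sizes; the
normalization choice is the user's). Tiers are low (< 9), mid (9–11,
boundaries inclusive) and high (> 11) on mean logCPM. Ex90 is the
smallest number of genes whose summed expression reaches 90% of the
total; it is scale- and order-invariant and unaffected by zero-expression
genes. The tier-vs-quadrant overlay is a 3×4 contingency table with a
chi-squared independence test (warning when expected counts drop below
5): association would indicate that composition drives expression,
independence that it does not.

## The synthetic-data generator

The generator provides every input with known truth. An ancestor genome
of valid ORFs (default 150 genes, mean 300 bp, 50% GC — free-living-like
composition at desk scale) spawns descendants (default 10, the size of a
typical comparative panel) by:

- **Substitution.** Each ancestor gene draws one latent erosion intensity
  from a Gamma(shape 1.2, mean 1); per descendant, per-site substitution
  probability is `erosion_mean × intensity` (capped at `max_gene_rate`).
  New bases are A/T with probability `at_bias` = 0.8. Start/stop codons
  are preserved and substitutions never create internal stops, so
  annotation stays intact. Because one latent intensity drives both %GC
  erosion and identity decay, the generator embodies exactly the coupling
  the conservation statistics are designed to detect — making it the
  correct positive control, and meaning that recovery tests validate the
  machinery, not the biological claim.
- **Loss.** Gene loss probability is logistic in the eroded gene's
  current %GC (baseline 0.08, midpoint 42%, slope 0.15), echoing the
  observation that low-GC genes are the ones being purged; a protected
  fraction (0.2, the essential-gene analogue) is never lost.
- **Splitting** (p = 0.02/gene): an internal codon becomes a stop and the
  following one a start, producing two annotated fragments whose summed
  protein length equals the parent's.
- **Duplication** (p = 0.01/gene): a tandem copy.
- **Inversions** (Poisson rate 0.3/genome, 2–8 genes): local order
  reversed and strands flipped; plus rare isolated strand flips (0.005).
- **Origin rotation** and intergenic shrinkage (30%) complete the
  descendant.

Default erosion (`erosion_mean` 0.25) was set so descendants fall in the
deep-erosion regime of real reduced genomes: residual identity around
60–70%, a minority of genes beyond RBH recognition, GC–identity Pearson
r ≈ 0.75. `SimulationConfig.mild()` (erosion 0.06, per-gene rate capped
at 0.2) defines the regime where every family remains unambiguously
recognizable; exact pan/core recovery is asserted there, because at deep
erosion family assignment is genuinely ambiguous — as it is for real
severely deteriorated genes.

Pileups are multinomial allele counts at Poisson depth over a strain
mixture with uniform sequencing error; expression counts are negative
binomial around tier-specific means defined at the nominal library size.
All randomness flows from one integer seed through independent named
streams.

What the generator does **not** emulate: codon-position structure (real
genes keep amino acids while synonymous sites saturate, so real data can
pair ~26% GC with ~50% identity — the simulator's composition and
identity move together more tightly); phylogenetic branch structure
(descendants are independent draws; the `two_clade` mode plants clade-
specific loss pools only for clustering tests); selection on intergenic
regulatory elements; and sequencing artifacts beyond uniform error.
Passing recovery tests therefore shows the pipeline is correct under its
stated model, not that the model captures every property of real
endosymbiont data.

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; GenBank conversion at the
  I/O boundary. Circular records linearize at position 0; origin-spanning
  features stay single genes with two-span locations.
- Pseudogenes are parsed, flagged, and excluded from protein-coding
  statistics by default.
- SDs are sample SDs (n−1). Intergenic gaps are signed; overlaps retained.
- Sliding-window %GC defaults to 1 kb windows, 200 bp step; only full
  windows are emitted, with optional wrap on circular genomes.
- The homopolymer census scans annotated gene spans on the forward strand;
  for the {A, T} base set runs are strand-symmetric. Both all-genes and
  CDS-only modes exist.
- OLS (statsmodels) fits identity ~ %GC + relative length; standardized
  coefficients are raw coefficients rescaled by SD ratios; rank-deficient
  designs are rejected naming the collinear columns. The length predictor
  is relative length (percent of the reference homolog), matching how
  length conservation is measured.
- Deterministic tie-breaks throughout: lexicographic gene ids in RBH ties,
  first traceback in alignment, '+' majority on even strand splits without
  a reference.

## Problem sizes

Tests and the acceptance script run desk-scale simulations (150-gene
ancestors, ten descendants, ~50 kb genomes, 500× pileups at 40 sites,
150-gene expression tables, 100 regression replicates) — large enough for
the statistical assertions, small enough to run in well under a minute
per stage on one CPU. All sizes are configuration, not constants.

## Known limitations

- RBH is exact all-vs-all alignment, O(n·m) alignments; fine for reduced
  genomes (hundreds of genes) against one reference, not built for
  multi-thousand-gene all-vs-all scans.
- Syntenic blocks ignore circular wrap-around, slightly overcounting
  blocks split across the chosen origin.
- The array's per-genome order invariant is relaxed inside inversions by
  construction (an inverted segment cannot read in genomic order in a
  shared row ordering).
- Indel effect annotation is per-start-position and does not re-translate
  downstream of the indel.
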