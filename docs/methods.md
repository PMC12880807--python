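# Methods

`conegrn` re-implements, as a tested library, the analysis pipeline used to
compare gene-regulatory programs of photoreceptor development between a
cone-dominant species and mouse from paired single-cell RNA and ATAC data:
cis-regulatory element classification, peak-to-gene linking, TF-binding-site
prediction with footprint filtering, signed regulon inference, key
cone-promoting-TF scoring, cross-species differential expression and motif
activity, and conserved-enhancer calling. Because the full deposited
datasets are not required to develop or test the method, the package ships a
synthetic two-species multiome generator with planted ground truth; every
recovery statement in the test suite is made against that truth.

## Statistical primitives

* **Marker test.** Differential comparisons use the two-sided Wilcoxon
  rank-sum test (the default behind the marker-finding tools the original
  analysis cites). The exact null distribution is used when the pooled
  sample has at most 20 tie-free observations; otherwise a normal
  approximation with tie and continuity correction (scipy's
  `mannwhitneyu`). The exact path is verified against full rank-split
  enumeration for all splits with total n ≤ 12.
* **FDR.** Wherever an "adjusted p" or FDR threshold appears, the
  Benjamini–Hochberg step-up procedure is applied. Note that BH is not
  idempotent as an operator on arbitrary p-vectors (re-running it rescales
  by n/rank again); the implementation is checked against statsmodels and
  the monotonicity/bounding properties instead.
* **Hypergeometric enrichment** is computed in log space
  (`hypergeom.logsf`), exact to ≤1e−10 relative error against direct
  binomial-coefficient summation for populations up to 60.
* **Fold changes** are `log2((mean_a + 1)/(mean_b + 1))` on depth-scaled
  log1p-normalized expression (scale 10,000). This normalization stands in
  for the original variance-stabilizing pipeline, which is out of scope;
  all fold-change thresholds in the package operate on this scale.

## Element classification

An accessible element carries a histone mark when it overlaps a called peak
for that mark AND its length-weighted mean signal within the element
exceeds 2.5 (strictly; uncovered bases count as zero signal, which
penalizes sparse coverage consistently). Classes are assigned with
precedence H3K4me3+ → TSS, else H3K27ac+ → aEnhancer, else H3K4me1+ →
pEnhancer, else unclassified. The precedence resolves multi-positive
elements, which the published rules leave implicit. A bivalent-TSS flag
(H3K4me3+ ∧ H3K27me3+) is available but never changes the class and is off
by default, because no classification rule for it is stated.

## Peak-to-gene linking

Single-cell accessibility is too sparse for per-cell correlation, so cells
are aggregated into pseudo-cell groups: k-means on the top 30 principal
components of normalized expression supplies centroids, and cells are then
assigned round-robin (each centroid in turn claims its nearest unassigned
cell), which makes group sizes equal to within one cell and the grouping
deterministic. The default group count is `n_cells / (2 × min_size)`
capped at 100, with `min_size` 20.

For every peak within 500 kb of a gene's TSS (distance measured TSS to the
nearest peak edge, 0 for overlap), the Pearson correlation between
group-mean normalized accessibility and group-mean normalized expression is
computed, with a t-distribution p-value (df = groups − 2) and BH correction
over all tested pairs. Cis-element categories per gene, assigned with
precedence TSS > gene body > intergenic and mutually disjoint:

1. **TSS peaks** — overlap the 1-kb window centred on the TSS (read as
   TSS ± 500 bp); no correlation requirement.
2. **Gene-body peaks** — overlap the gene body, r > 0.25 and FDR below the
   caller's threshold (0.05 for GRN assembly, 0.01 for cross-species
   element counting; both live in the config and the caller picks).
3. **Intergenic peaks** — within 500 kb, overlapping no target gene's TSS
   window or body, same correlation requirement.

## TF-binding-site prediction

PWMs are probability matrices with a configurable pseudocount; log-odds are
in bits against an i.i.d. background (uniform by default, configurable).
The score threshold at motif p-value 5e−5 is computed from the exact null
score distribution by dynamic programming over positions. DP states are
keyed on partial score sums rounded to 1e−9; all score comparisons carry a
1e−7 slack so that mathematically tied scores whose float representations
differ in the last bits are never split, and the returned threshold is the
smallest achievable score whose tail probability stays below p. A
coarse-binning fallback (1e−4 bits) guards motifs long enough to overflow
the state dictionary; the bundled synthetic motifs (length 10) never hit
it. Both strands are scanned; windows containing N are skipped; a
minus-strand hit covers the same genomic bases as the plus-strand window at
that offset.

Footprint filtering: for a candidate site, S_center is the mean normalized
Tn5 insertion signal over the site and S_left/S_right the means over the
two abutting flanks, each three times the site width. A site is retained
iff S_left − S_center > 0.05 AND S_right − S_center > 0.05 (strict, with a
1e−9 guard so averaging round-off cannot promote an exact-boundary
difference). Insertion signal is expected on a normalized scale
(counts per base over depth); sequence-bias correction of the insertion
profile is out of scope. Per cell type, TFs with mean normalized
expression below 0.1 are excluded before scanning.

## Regulon inference and key-TF scoring

TF–target importances come from a gradient-boosted tree regression
(xgboost: 100 trees, depth 3, learning rate 0.1, subsample 0.9, fixed
seed, single thread) of each target's normalized expression on all TF
expressions, with per-target total split gain normalized to sum to 1 over
TFs — this gives the 0.1 importance cutoff a defined scale, since the
cited tool's raw importance scale is unstated. An edge is positive iff
importance > 0.1 and Pearson r > 0.05, negative iff importance > 0.1 and
r < −0.05. A regulon (cell type, TF, peak, target, sign) requires the peak
to lie in the target's cis-element set and to carry a footprint-passing
binding site for the TF in that cell type; exact duplicates are removed,
and TF→target regulons are the peak-collapsed deduplication.

Cone-specific genes are cone-upregulated markers versus the other
late-stage neuron types (BC/photoreceptor precursors and rods by default;
configurable), at log2FC > 0.3 and BH-adjusted p < 0.01. Key activators:
with the positive GRN's distinct targets as population, each TF's distinct
positive targets as draws and the cone-specific ones as successes, TFs
with upper-tail hypergeometric p < 1e−6 and coverage > 0.2 are kept,
ranked by cone-specific target count (ties broken by p, then TF id — the
published ranking states only the primary key) and truncated to 30.
Population and successes count distinct genes, not regulon rows.

## Cross-species comparison

Species-a genes are collapsed onto species-b orthologs (counts of
many-to-one genes summed per cell), matrices merged and re-normalized.
DEGs are Wilcoxon tests per gene in five contrasts (RPC, N.RPC, BC/Pho
precursor, cone–cone, cone–rod), retained at |log2FC| > 0.35 and
p < 1e−6 (strict). Merged DEG profiles — mean normalized expression over
the 10 species × cell-type groups, row-standardized — are clustered by
k-means with k = 8 (10 restarts, fixed seed). Regulatory-element counts
per conserved gene pair use links at FDR < 0.01, are normalized by the
per-species mean count per gene, and compared per cluster with a paired
t-test (a degenerate cluster with all-zero differences reports the p = 1
sentinel).

Conserved elements: candidate peak pairs are the TSS-window elements of
each one-to-one ortholog gene pair. Scores are Smith–Waterman local
alignments with match +1, mismatch −1 (the original states only the gap
parameters; match/mismatch are configurable) and affine gaps costing
2 + L for a length-L gap (open −2, extend −1 in the cited aligner's
convention — implemented via Biopython's `PairwiseAligner` with
open_gap_score −3 and extend_gap_score −1, verified exactly against an
independent Gotoh DP). Each pair is scored forward and reverse-complement
and the maximum kept; N matches nothing. A normal distribution is fitted
by maximum likelihood to ALL scores (including any genuinely conserved
pairs, which inflates the threshold slightly) and pairs strictly above the
upper 5% quantile are conserved. Because local-alignment scores have a
Gumbel-like right tail, the realized flag rate on pure-random pairs is
~7.5% rather than the nominal 5%.

## Motif activity

For a motif annotating peak set S, a cell's expected fragment count is its
depth times S's fraction of all counts; the raw deviation is
(observed − expected)/expected. Each motif is standardized against 50
background peak sets drawn per peak from a 10 × 10 quantile grid of
(GC fraction, mean accessibility) — singleton grid cells merge into their
nearest neighbour — giving a z-score per cell (z = 0 where the background
spread is zero). Cell-type-specific motifs: one-vs-rest Wilcoxon on z,
BH-adjusted p < 0.01 and avg_diff (difference of group mean z) > 2,
positive only. Cross-species differential motifs additionally require the
motif's gene (an explicit motif→gene table; no name matching) to change
expression in the same direction in the same contrast; the merged set is
ordered by average-linkage hierarchical clustering of group-mean z
profiles on Euclidean distance.

## The synthetic study

The generator emulates the data the pipeline assumes, with a planted truth
used as the recovery oracle. Defaults (per species): 1,500 cells over five
cell types (RPC 25%, N.RPC 20%, BC/Pho precursor 20%, cone 20%, rod 15%),
300 genes of which 25 are TFs, 1,200 peaks of 200 bp on two chromosomes
(genes every 40 kb, 10-kb bodies, alternating strands).

* **TF activity.** Each TF has a primary cell type at full activity and a
  distinct secondary type at partial activity (level 0.35 or 0.18), so no
  two TFs share an identical pattern — co-active TFs remain separable by
  the tree model, which is the property real GRN inference relies on. The
  five cone TFs have primary Cone; their secondaries are restricted to
  progenitor types so their targets stay cone-specific against the
  late-neuron comparison set. Two cone TFs are species-a specific.
* **Counts.** RNA and ATAC counts are negative binomial with shared
  dispersion 2. TF counts are drawn first from their cell-type means
  (high 6, floor 0.02); each planted target's per-cell mean is then
  `base × effect^a`, where `a` is its own TF's realized saturating
  activation in that cell — the TF→target dependence exists at single-cell
  resolution, as GRN inference assumes. The planted effect size is 5
  (a typical marker-gene magnitude; on the log1p-normalized scale this
  yields log2 fold changes comfortably above the 0.3/0.35 thresholds).
  Negative targets are repressed where their TF is active.
* **Regulons.** Each cone TF has 18 positive targets, other TFs 7 positive
  and 2 negative, all target sets disjoint (270 of the 275 non-TF genes).
  Positive-regulon peaks alternate between gene-body and intergenic
  placement and gain accessibility with TF activity; negative-regulon
  sites sit in the constitutively accessible TSS-window peak. The TF's
  motif consensus (length 10, sharply informative columns) is embedded at
  the peak centre, on alternating strands.
* **Footprints.** Insertion signal is Poisson per base at normalized rate
  0.5, with bound sites protected to 0.4× that rate in cell types where
  the TF is expressed, at depth 100. These values separate bound from
  unbound cleanly at the 0.05 criterion: the expected flank-minus-centre
  difference at a bound site is 0.3 versus sampling noise of ~0.03.
  Within the full dataset, insertion values are binned at 10 bp away from
  planted sites (per-base near them); averaging over a footprint window
  makes this statistically equivalent at lower cost.
* **Histone signal.** The defining mark of each element class has a peak
  call over the element and signal ~N(5, 0.7); all other marks lack a call
  and have signal ~|N(1, 0.5)|, putting unclassified elements below the
  2.5 threshold with probability >0.999.
* **Conservation.** 10% of genes have conserved promoter cores: the
  species-b promoter is the species-a sequence with 10% per-base
  substitutions, every second one reverse-complemented. All other
  sequences are independent and uniform.
* **Orthology.** 10% of species-b genes have two species-a copies (the
  duplicate at half expression) to exercise many-to-one collapsing.

What the generator does **not** emulate: doublets and ambient
contamination, batch effects, pseudotime continuity, sequence-specific Tn5
bias, overlapping regulon target sets, and realistic motif redundancy
across TF families. Passing recovery tests therefore shows the pipeline's
rules and statistics are implemented correctly and identifiable under the
model's own assumptions — not that the thresholds are optimal on real
retina data.

## Determinism and problem sizes

Every stochastic stage consumes an independent substream spawned from the
single config seed (SeedSequence fan-out), so re-running with the same
config is hash-identical and adding a stage never perturbs earlier ones.
The test suite runs the full default study (2 × 1,500 cells) once as a
shared fixture (~1 minute); the run-to-run determinism check uses an
800-cell dataset, and null calibrations use 600–1,000 cells/genes and up
to 8,000 random sequence pairs — sizes chosen so each statistic's sampling
noise is small relative to the margin it is tested against.

## Known limitations

* The importance scale (normalized total gain) is a documented substitution
  for the cited tool's unstated scale; the 0.1 cutoff is configurable.
* The fitted-normal conservation threshold inherits the normal/Gumbel
  mismatch noted above.
* Motif p-values assume an i.i.d. background; dinucleotide models are out
  of scope.
* Cross-species differential motifs are reported for the species-a-up
  direction (positive avg_diff), mirroring the positive-only marker
  convention used for the cell-type-specific selection.
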