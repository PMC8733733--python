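# Methods

## Quantification

FPKM(g, s) = count(g, s) · 10⁹ / (length(g) · N(s)), with the library
size N(s) taken as the column sum of assigned counts — self-contained
and deterministic rather than an external "total mapped reads" figure.
Replicates are averaged arithmetically into (cultivar, stage) group
means. Replicate QC is Pearson correlation on log₂(FPKM+1), the
conventional scale for expression concordance; the pass threshold
defaults to r ≥ 0.84. A pair of constant replicate vectors has no
defined correlation and is reported as not-computable rather than
failed.

A homoeolog pair counts as *expressed* in a group when
max(FPKM_At, FPKM_Dt) reaches `min_fpkm` (default 1.0). The max rule is
deliberate: one-sided silencing is an extreme form of bias, and a
two-sided floor would remove exactly the pairs of most interest. The
floor itself is a convention; no analysis here is calibrated against a
particular choice, and it is configurable everywhere.

## Bias calling

Fisher's exact test needs integer counts, while fold change is a
statement about normalized expression. The caller therefore separates
the two roles:

* **significance** comes from the two-sided Fisher exact test on summed
  replicate counts of the two homoeologs against the remainder of their
  libraries, `[[sum_A, sum_D], [lib − sum_A, lib − sum_D]]`. Summing
  replicates before testing (rather than averaging) keeps the table
  integral; the library margins make the test scale-aware. The
  two-sided p sums hypergeometric point probabilities not exceeding the
  observed table's, computed from log-gamma so library-scale margins
  cost microseconds; relative accuracy is ~1e-12 on small tables and
  ~1e-7 when margins reach 10⁷–10⁸, far below any decision threshold.
  Ties in point probability are resolved with 1e-12 relative slack.
* **effect size** is judged on group-mean FPKM: |log₂ ratio| ≥ log₂(2).
  If one homoeolog has FPKM 0 and the other is at or above the
  expression floor, the ratio is reported as a ±∞ sentinel and passes
  the gate.

BH adjustment is applied within each (cultivar, stage) family across
its expressed pairs. The per-group direction verdict is an exact
two-sided binomial test of the At-biased count against half the biased
total, with direction reported only below p = 0.05.

Note the significance test's null is "counts split like the libraries",
not "equal FPKM"; when the two homoeologs differ in length the count
ratio differs from the FPKM ratio and the test is anti-conservative.
In practice the fold-change gate, which is evaluated on FPKM, is the
binding criterion; the simulator's null calibration (planted ratio 1,
length ratios up to 10×) measures a false-call rate under 1%.

Strict species consensus requires the identical call in every cultivar
of the species at that stage; a pair unexpressed in any cultivar is
excluded. The 8 interspecific categories are the strict Gh×Gb pattern
combinations excluding (no bias, no bias); "differing" drops the two
same-direction categories.

## Temporal clustering and postponement

Profiles are per-gene z-scores of log₂(FPKM+1) over the seven sampled
stages of each species' reference cultivar; exactly constant raw
profiles are excluded (constancy is judged on the raw range, since
floating-point summary statistics can report ~1e-16 spread for constant
input). Fuzzy c-means uses the standard alternating updates
(u_ij ∝ d_ij^{−2/(m−1)}, centers as u^m-weighted means) from seeded
random memberships until the objective changes by < 1e-6 or 300
iterations. Defaults: c = 9 clusters — several per key stage of a
7-point course; m = 1.25, the usual softness for standardized
expression data (m → 1 recovers k-means); assignment gate 0.5 on the
maximal membership. A point coinciding with a center takes full
membership there.

A cluster's peak stage is the stage of its center's maximum. For
cross-species comparisons peaks are restricted to 10/20/25 DPA — the
elongation and secondary-cell-wall stages both species sample — so
clusters peaking at 0–5 DPA contribute no peak stage. Ortholog pairs
are then classified once each: consistent (same key peak), postponed
10→20 / 10→25 / 20→25 (the *G. barbadense* copy peaks later), advanced
(earlier), or unassigned. Because cluster count, fuzzifier and gate are
free parameters of any such analysis, absolute cluster-census numbers
are configuration-dependent; the tests therefore validate planted-truth
recovery, not particular census values.

## Co-expression networks

Unsigned adjacency |cor|^β. β is the smallest candidate (1..20) whose
connectivity distribution fits a power law with R² ≥ 0.8 in a 10-bin
log-log regression, else the best-fitting candidate. The topological
overlap is

TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).

Modules come from average-linkage clustering on 1 − TOM with a *static*
cut: among the dendrogram's merge heights, the one maximizing first the
number of clusters meeting the size floor (default 30) and then the
number of genes assigned. This is a reproducible simplification of
dynamic tree cutting, adequate for recovering planted structure;
branch-shape heuristics are out of scope. Modules whose eigengenes
correlate above 0.75 are merged iteratively (closest pair first).

The eigengene is the first right-singular vector of the standardized
module matrix, scaled to unit variance and oriented to correlate
positively with the module's mean expression. kME is the Pearson
correlation of a gene with an eigengene; hubs are the top-3 kME members
(ties broken by gene id). A module's stage association is the stage
indicator with maximal |r| against its eigengene, with p from the t
distribution on n − 2 df. Whole-transcriptome runs keep the 2000
most-variable genes by default, the usual economy for topological
overlap matrices.

## Simulator

The generator reproduces the study layout: 4 *G. hirsutum* and 3
*G. barbadense* cultivars, the reference cultivar of each species
(TM-1, Hai7124) sampled at 0/1/3/5/10/20/25 DPA and the others at 10
and 20 DPA, 3 replicates, 2×10⁷ fragments per library, and ~3000
homoeolog pairs per species by default (a desk-scale stand-in for the
~21k-pair genome; every rate estimated here is per-pair, so the scale
affects only Monte-Carlo error). Expected expression per gene:

* a per-pair baseline FPKM, log-normal(ln 10, 1), shared by the two
  homoeologs and drawn per species;
* a temporal multiplier: discrete Gaussian bump over the ordered stage
  axis centered at the pair's planted peak, width one stage, floored at
  5% of baseline;
* planted bias (10% of pairs): ±1 log₂ unit on the At/Dt copies
  (2 log₂ units of planted ratio), direction split 50:50 so that both
  the null and skewed alternatives of the direction test are exercised;
* planted postponement (10% of non-module pairs): the *G. barbadense*
  copy's peak moves one shift later (10→20 or 20→25, alternating);
* planted modules (3 × 60 genes = 30 pairs each, *G. hirsutum*): a
  centered one-hot contrast at the module's key stage (one-hot rather
  than bump-shaped so different modules' factors are nearly
  uncorrelated, cor = −1/6, and are not erased by eigengene merging),
  gene loadings uniform[0.6, 1], and a per-sample log-normal residual
  (sd 0.5). Factor and residual apply to *both* homoeologs of a module
  pair, so module structure never masquerades as subgenome bias. Each
  module's seed pair carries loading 1 and no residual; its At gene is
  the module's generating hub.

Observed counts are negative binomial with mean
FPKM · length · library / 10⁹ (lengths uniform 500–5000 bp) and fixed
dispersion 0.05 — the standard single-parameter RNA-seq noise model.
Everything is deterministic given the seed.

What the simulator does **not** emulate: mapping bias between
subgenomes, isoform structure, batch effects, cultivar-specific
expression differences beyond sampling noise, and correlated biological
replicates. Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under the declared noise model,
not robustness to alignment artifacts.

### Recovery metrics

Bias sensitivity is measured over planted-biased pairs that passed the
expression filter in a group (a pair silenced below the floor is not a
caller failure; the count of untested planted pairs is reported
alongside). An optional `min_mean_fpkm` argument restricts scoring to
well-expressed pairs. Empirical FDR is the planted-null fraction among
biased calls. Postponement recovery scores per shift class against
per-gene planted truth; module recovery is the adjusted Rand index over
the planted-module genes, with the unassigned label counting as its own
class.

## Numerical conventions

* Output floats carry 12 significant digits, scientific notation below
  1e-4; a write/read round trip is value-identical at that precision,
  and identical runs are byte-identical.
* Z-scores and eigengene variances use the population convention
  (ddof = 0).
* Hub and edge orderings break ties lexicographically by gene id, so
  all network outputs are deterministic.
* Degenerate inputs: zero library size, missing gene length, fewer than
  8 samples for a network, fewer profiles than clusters, and mixed
  consensus patterns passed to the interspecific classifier are all
  hard errors; constant genes in a network get zero correlation with a
  warning.

## Known limitations

* The exact-test construction (counts vs library margins) is one
  reading of "compare FPKM with an exact test"; alternatives (e.g.
  pseudocounted ratio tests) would change p-values but not the
  FPKM-gated calls in any regime the simulator probes.
* The static tree cut can split a module whose internal topology is
  strongly uneven; dynamic cutting would be the upgrade path.
* cis/trans attribution, expression-level dominance, GO/KEGG enrichment
  and read-level simulation are out of scope.
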