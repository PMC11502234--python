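# Methods

## Scope and data model

The package covers the analysis chain from a raw gene × sample count matrix
to dysregulated-gene calls, coexpression modules and their driver genes,
protein-interaction-network (PIN) hub structure, and the behavioral %PPI
metric. All inputs are plain text (counts TSV, metadata TSV, STRING-dialect
edge lists, GMT gene sets, trial CSVs); in memory the pipeline passes
pandas DataFrames, an `ExprMatrix` wrapper carrying provenance flags, and
networkx graphs.

## Differential expression (`degflow`)

Counts are normalized within sample to counts per million and transformed
as `log2(CPM + 2)`. The pedestal of 2 keeps zeros finite and pins the
minimum attainable value at 1; the downstream noise floor of 2.25 (a
config parameter) lives on this scale, corresponding to ≈ 2.8 CPM.

Cross-sample normalization is cyclic loess: for each sample pair, the
difference M is smoothed against the average A (loess fraction 0.3, three
full cycles over all pairs — common smoother settings, exposed in config)
and half the fitted trend is attributed to each sample.

Outlier samples are flagged from covariance-based PCA: samples are scored
on the first two principal components of the gene-centered matrix, and a
sample is flagged when its distance from the score centroid is (i) more
than 3 robust SDs (1.4826 × MAD) above the median on the log-distance
scale and (ii) at least double the median distance. Null distances are
Rayleigh-like and right-skewed, so a threshold on raw distances flags the
skew tail even in homogeneous cohorts; the log transform symmetrizes the
null, and the doubling guard requires a practically large excursion.
In simulated cohorts this leaves ≥ 95% of clean datasets unflagged while
always catching a sample whose values were independently permuted (a proxy
for a degraded library). Flagged samples are dropped and normalization is
repeated without them.

Batch effects are removed gene-wise by fitting `value ~ trait + batch` and
subtracting the centered batch contribution, which leaves trait effects
intact and is exact (to 1e-8) for additive shifts. Perfect trait/batch
confounding raises an error naming the aliased columns.

Genes must exceed the noise floor in at least one sample to survive
filtering; surviving values below the floor are raised to it. The test is
then a per-gene ANCOVA `value ~ trait + batch + sex` by OLS; `p_trait` is
the two-sided t-test on the trait coefficient, and `log2FC` is the
covariate-adjusted test-minus-reference difference, so `linearFC =
2^log2FC` is signed test/reference. A gene is called when p is below the
cut (0.05 or 0.1) *and* `linearFC ≥ 1.25` or `≤ 0.8`. P-values are
unadjusted by default — the covariate adjustment is the "correction" —
with Benjamini–Hochberg available as a config switch; which convention a
given study intends is often ambiguous, so both are provided.

Measured on the generator's default conditions (2,000 genes, 6 vs 6,
two batches, balanced sex, NB dispersion 0.1): null fraction of p < 0.05
≈ 0.05, and ≥ 80% power for planted 2-fold changes at the joint p/FC bar.

## Coexpression modules (`modulenet`)

The network is unsigned by default, `a_ij = |cor|^β` (signed and biweight
midcorrelation variants available); β is the smallest power whose
scale-free fit R² reaches 0.8, with a plateau fallback (the first power
after which the fit curve stays within 0.01) when no candidate reaches the
target — on structureless data this pushes β high, which is the desired
behavior (noise adjacency collapses toward zero). Topological overlap
follows the standard formula; `tom_from_adjacency` is exact against a
double-loop oracle to 1e-10.

Module detection clusters `1 − TOM` by average linkage and cuts the
dendrogram adaptively rather than at a fixed height:

1. **Cores** are the dendrogram's *birth nodes* — branches that first
   reach `min_size` (default 30) genes — found below the median merge
   height. Coherent modules coalesce early (in simulations their birth
   heights sit below the 25th percentile of merge heights) while
   unstructured genes only agglomerate near the top of the tree (birth
   heights above the 75th percentile), so the median is a robust,
   scale-free ceiling. On pure-noise data no core forms and all genes stay
   unassigned.
2. **Admission**: remaining genes join the core whose eigengene they
   correlate with most strongly, when that |kME| is significant under BH
   control at α = 0.05 (Bonferroni-scaled over candidate modules). A
   significance rule rather than a fixed kME cutoff makes admission adapt
   to both the sample count and the background size.
3. **Merging**: modules whose eigengenes correlate above 0.75
   (merge height 0.25) are fused; modules below `min_size` dissolve into
   "unassigned". Labels follow the conventional color order by size.

This cut is this package's own design: it reproduces the intended behavior
of dynamic tree cutting (planted-module recovery with adjusted Rand index
≥ 0.7 on the 1,000-gene two-module benchmark; ≥ 80% of genes unassigned on
pure noise) with two interpretable parameters.

Eigengenes are unit-norm first principal components of the standardized
module expression, oriented so the mean member correlation is
nonnegative. Module–trait statistics are Pearson correlations of
eigengenes with 0/1-encoded covariates and their exact t-based p-values
(n − 2 df). GS is the gene–trait correlation, MM the gene–eigengene
correlation; the per-module GS~MM correlation (on absolute values)
summarizes whether trait-associated genes are central to their module.

**Permutation validation** reshuffles gene→module labels (sizes
preserved), recomputes eigengenes and module–trait correlations per
permutation (default 40), and reports whether the observed module beats
every permutation on both |r| and p — an envelope criterion rather than a
p-value, mirroring how such clouds are read with 40 draws.

**Drivers** are genes at or above the module's 95th percentile of MM (ties
included). The deletion test removes driver rows/columns from the
adjacency, *recomputes* TOM on the reduced network, and compares the
module's intra-module edge weights before vs after by two-sample KS. The
recomputation matters: deleting high-connectivity drivers removes their
shared-neighbor support, so the entire remaining weight distribution
shifts left; merely dropping driver-incident edges from a fixed TOM caps
the achievable D at roughly twice the driver fraction. With adjacency
weights (config option) deletion cannot change pairwise values and the
test reduces to that subset comparison.

### Known limitation: the permutation envelope at n = 12

With 12 samples, the first PC of *any* 150-gene set spans a direction in
an 11-dimensional space, and its correlation with a fixed binary trait can
reach 0.6–0.95 by chance; moreover, when trait-linked genes make up more
than a few percent of the matrix, permuted gene sets inherit enough of
them that their eigengene aligns with the trait axis almost surely. The
envelope study therefore runs at the full ~15,000-gene transcriptome
scale, where trait-linked genes are a realistic small minority. Even
there, a module built at trait correlation 0.9 beats all 40 permutations
in most seeds, but one built at 0.75 (observed |r| ≈ 0.75 ± 0.13) overlaps
the distribution of permuted maxima and passes in only about half of
seeds. The envelope is thus a demanding criterion whose replication rate
at these sample sizes is intrinsically limited — a single successful
envelope on one dataset does not imply it would recur in most replicates.
`scripts/acceptance.py` reports the measured rates.

## PIN topology (`graphtop`)

STRING-format edges are filtered on a combined score recomputed from the
*selected* channels only (default experiments, databases, fusion) with the
prior-corrected product rule at p₀ = 0.041, so excluded evidence (e.g.
text mining) cannot carry an edge over the 0.9 threshold; nodes left
without edges are dropped.

MCC sums `(|C|−1)!` over the maximal cliques containing a node,
enumerated exactly by Bron–Kerbosch with pivoting under a configurable
guard (10⁶ cliques) against pathological inputs. A node whose neighbors
share no edges has only size-≤2 maximal cliques through it, so the
conventional "MCC = degree" special case is implied by the formula.
Hub selection takes the top 10 by dense rank, retaining boundary ties.
Validated against an exhaustive subset-filtering oracle on random graphs
and closed forms (`MCC(K_n) = (n−1)!`, star centers).

Topological coefficients follow the NetworkAnalyzer convention:
`TC(v) = mean_u J(v,u)/k(v)` over nodes u sharing at least one neighbor
with v, `J = |N(v) ∩ N(u)|` plus 1 if adjacent, and `TC = 0` for degree
≤ 1. In preferential-attachment graphs TC falls steeply with degree
(Spearman ρ ≈ −0.95), the signature of hub-and-spoke organization.

Node deletion removes the listed nodes plus any nodes thereby
disconnected, reporting node/edge/component counts and average degree
before and after. Seeded growth admits candidates only through direct
edges to the growing seed component, iterated to a fixpoint, then induces
all edges among included nodes. Enrichment is the one-sided hypergeometric
upper tail with odds ratios from the 2×2 table (Haldane 0.5 correction
when a cell is zero) and BH adjustment.

## Startle metrics (`startle`)

Baseline startle is the mean amplitude over startle-alone trials. %PPI is
reported as percent inhibition, `100·(1 − mean_prepulse/baseline)`,
floored at 0% — the capping rule only makes sense for the inhibition form,
since a ratio of nonnegative amplitudes cannot go negative; the raw
response ratio is retained as a diagnostic column. A trial type is
sensitized when its baseline-normalized response exceeds 100%, so %PPI > 0
and sensitization are mutually exclusive per trial type.

## Synthetic data (`synthio`)

Counts are gamma-Poisson (negative binomial, var = μ + αμ²) around
log-normal gene baselines on the CPM scale, multiplied by log-normal
library sizes (default mean ≈ 33.3 M reads, matching deep bulk libraries).
Defaults emulate a two-genotype mouse design: 6 samples per genotype,
3 per sex, two sequencing batches (batch assigned in blocks within
genotype so that trait, batch and sex are mutually unaliased), dispersion
0.1, 5% of genes at a planted 2-fold change (half up, half down).
Modules are planted through one latent factor per module, constructed as
`ρ·z_trait + √(1−ρ²)·noise` so the factor–trait correlation is ρ in
expectation, entering member genes through loadings uniform in (0.5, 1);
batch adds gene-wise N(0, 0.2) offsets on the log2 scale. Interactomes
are preferential-attachment backbones with per-channel evidence scores
and an optional clique planted on the lowest-degree nodes; for
fragmentation studies the single-attachment (m = 1) backbone is used, as
it produces the hub-and-spoke topology in which hub deletion visibly
shatters the network. All generators draw from child streams of one root
seed and are bit-reproducible.

What the generator does *not* emulate: count over-dispersion
heterogeneity across genes, gene–gene correlation beyond the planted
factors, GC/length biases, isoform structure, and any read-level
artifacts. Passing recovery tests on these simulations shows the chain is
correctly implemented and calibrated under its assumed generative model,
not that it is robust to everything real libraries do.

## Study sizes

Validation studies are sized for a single CPU: DEG calibration/power at
2,000 genes; module recovery at the 1,000-gene two-module benchmark
(20 seeds); the permutation envelope at 15,000 genes (20 seeds; no TOM is
needed for that study); driver deletion at 1,000 genes; fragmentation on
500-node interactomes (20 seeds); the MCC oracle on 100 random graphs of
up to 15 nodes.
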