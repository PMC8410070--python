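# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Quality control and normalization

Cells are removed when the mitochondrial count fraction is **greater
than** 0.10 or the number of detected genes is **fewer than** 200; both
inequalities are deliberately strict, so a cell at exactly 10% / exactly
200 genes is retained. Mitochondrial genes are identified by the symbol
prefix `MT-` (human convention; the prefix is a parameter). The filter is
idempotent by construction.

Normalization is per-cell: counts are scaled to a common depth (default
scale factor 10,000 — i.e. CP10K) and transformed with the natural
logarithm, `ln(1 + x)`. Natural log is used everywhere in the package; a
zero count always maps to exactly zero. Because the transform only uses
within-cell totals, normalization commutes with cell subsetting.

## Clustering and annotation

Clustering is top principal components (default 20, randomized SVD with
a fixed seed) of centered normalized expression, followed by either
k-means (k given; `n_init=10`, seeded) or a kNN-graph Leiden partition
(resolution given; seeded). Cluster ids are relabelled contiguously in
order of first appearance, so output is platform-stable. The contract of
this stage is recovery of planted structure, not replication of any
specific published clustering; both built-ins are exposed and the choice
is reported in the labels' `method` string.

The whole atlas is clustered finer than the class count (default k = 12)
and each cluster is then assigned the cell class whose canonical marker
panel has the highest mean normalized expression in the cluster; ties
break by declared panel order and are recorded. Clustering directly at
the class count would conflate EC subcluster structure with class
structure — the endothelial compartment alone spans five subclusters.

### EC selection and doublet flagging

EC-cluster cells are retained. A cell is flagged as a heterotypic
doublet and removed when, for some non-EC panel:

1. its panel score exceeds the configurable quantile (default 0.99) of
   that score among EC-cluster cells, **and**
2. its EC score exceeds the median EC score of the non-EC background
   (the cell is genuinely EC-positive), **and**
3. its panel score is at least `min_partner_fraction` (default 0.5) of
   that class's mean score in its own cells — a 50:50 doublet carries
   roughly half of the partner signature, while upper-tail noise in a
   singlet EC does not approach it.

Condition 3 is what makes the rule robust: with 3-gene canonical panels
the upper 1% tail of singlet scores would otherwise be flagged for every
panel. The rule, its parameters and every removal are reported; it is a
declared heuristic of this package, not a reproduction of any published
doublet method.

## Statistical primitives

The rank tests are implemented from first principles because their exact
small-sample behaviour is part of the package's contract.

* **Rank-sum (Mann–Whitney).** Midranks for ties. For pooled sizes up to
  `exact_limit` (default 14, configurable) the exact null is computed by
  a subset-size × rank-sum dynamic program over the observed (tied)
  ranks — the identical distribution to enumerating all C(n1+n2, n1)
  group assignments, verified against a literal enumeration oracle in the
  tests. The two-sided p-value is the null probability of a statistic at
  least as far from its mean as observed, which equals brute-force
  permutation on the raw data. Above the limit: normal approximation
  with tie-corrected variance and a 0.5 continuity correction.
* **Signed-rank (paired Wilcoxon).** Zero differences dropped and
  counted; exact sign-pattern distribution by convolution up to 20
  informative pairs (configurable), tie-corrected normal approximation
  beyond.
* **Approximation accuracy.** With moderate ties (integer-like data with
  ~10 distinct levels) the approximation agrees with the exact p to
  within 0.02 worst-case for group sizes around 15–25, and improves with
  n. With *extreme* ties (≤ 6 distinct values at small n) the exact null
  has probability atoms larger than 0.02, so no smooth approximation can
  track it to that tolerance; for such data use the exact mode, which is
  cheap far beyond the default switch point thanks to the dynamic
  program.
* **Multiplicity.** Bonferroni, with m defaulting to the number of genes
  tested within the specific comparison (a global-m alternative is a
  parameter).
* **Effect size.** Natural-log fold-change of pseudocounted (default 1)
  means of `expm1`-scale normalized expression.
* **Correlation.** Pearson (default) or Spearman over cells; zero-
  variance genes are excluded and listed; the matrix is symmetrized,
  clipped to [−1, 1], unit diagonal.

Marker discovery uses a vectorised row-wise implementation of the
large-sample rank-sum path; the tests assert it is numerically identical
to the scalar test per gene.

## Marker discovery and differential splits

Markers are up-regulated only: a (gene, cluster) record is kept when the
Bonferroni-adjusted two-sided p is below alpha (default 0.05) and the
fold-change is positive. Ranking is ascending raw p, then descending
fold-change, then lexicographic symbol — fully deterministic. "Top 50"
takes the first 50 of that ranking (the p-then-fold order is a package
choice; the alternative fold-first ranking is one parameter away).
EC-enriched genes use the same machinery with exactly two groups (EC vs
all other cell classes); the core-vs-periphery split tests only the
EC-enriched genes among EC cells and partitions significant genes by
fold-change sign, so the up and down sets are disjoint subsets of the
input domain by construction.

## Cross-atlas similarity

Gene symbols are case-normalized before Jaccard comparison (both atlases
human; no ortholog mapping in this stage). The similarity→dissimilarity
transform is `d = 1 − J` by default (`sqrt(1 − J)`, which is metric for
Jaccard, is a parameter). Classical MDS clamps negative eigenvalues to
zero and reports the clamped mass — `1 − J` need not be Euclidean — plus
a residual stress. Axis signs are fixed by making each axis's
largest-magnitude loading positive, so coordinate files are reproducible
across platforms.

## BBB modules

Criterion boundaries follow their wording exactly: (a) *at least* 100
CPM is inclusive; (b) *more than* 2-fold is strict, and requires a
rank-sum p < 0.05 against each of the four peripheral organs separately
on replicate CPM values; (c) *no less than* brain vasculature is
inclusive. With the exact two-sided rank-sum, 3-vs-3 replicates have a
p-value floor of 2/20 = 0.1, so criterion (b) is only decidable with at
least 4 replicates per group; the synthetic panel uses 5. The rank-sum
choice for (b) is this package's (the provenance of such modules rarely
states the test); a t-test hook is exposed.

Homolog mapping resolves one-to-many rows by keeping the
lexicographically smallest target and logging alternatives; unmapped
genes move to a `dropped` list in the provenance chain, never silently.
Detection restriction keeps genes nonzero in ≥ `min_cells` (default 1)
cells. Provenance sizes are monotone: raw ≥ homolog-mapped ≥ detected.
Every gene ever considered carries an audit record naming the criteria
it passed or failed.

Module co-expression reports mean off-diagonal correlation within each
module and across modules, with genes ordered by average-linkage
clustering of 1 − r for stable block display.

## Anatomic mapping

The microvascular score is the arithmetic mean of linear-scale
expression over the vascular-enriched panel (geometric mean is a
parameter); the panel itself is an input file, never hardcoded.
Log-scale input must be declared with an explicit flag — auto-detection
is refused. Because the score is linear in the sample column, dividing
by it makes the whole enrichment profile exactly invariant to rescaling
any sample, which the tests check to 1e−12 relative tolerance.

## The synthetic generator

Counts are negative binomial, `Var = μ + φμ²` with dispersion φ = 0.4,
around per-cell expected expression composed multiplicatively from:
log-normal gene base weights (σ = 1.2); class marker programs (markers
×e^1.5 for the 150-gene EC program, ×e^2.0 for other classes' 50-gene
programs, ×0.05 outside their own class — canonical markers in tissue
are class-specific, and cross-panel annotation is only meaningful in
that regime); five EC-subcluster marker programs (50 genes ×e^2.0);
core-vs-periphery programs inside the EC program (40 genes ×e^1.0 in
core, 20 in periphery); mild per-patient shifts (log-normal σ = 0.05);
and a latent per-cell "barrier state" that multiplies the planted core
BBB module by e^{0.3b} and the dysfunction module by e^{−0.3b} in every
cell, creating positive within-module and negative cross-module
correlation without shifting EC-vs-rest means. Library sizes are
log-normal (mean 5,000, σ = 0.25). Default scale is 3,000 cells × 2,000
genes from 4 patients — the planted structure of a ~10⁵-cell study at
desk scale.

QC failures are planted exactly (half high-mito with target fraction
0.20–0.35, half tiny-library with < 200 total counts); doublets (default
0.5% of cells) average an EC profile with a random non-EC class profile
at 1.8× library size. Regular cells target mitochondrial fractions of
0.01–0.06, several standard deviations below the 0.10 threshold.

The bulk organ panel plants brain-enriched genes at 10-fold enrichment
with 5 replicates and 5% log-normal noise, plus decoy families violating
exactly one criterion each (brain CPM 50; 1.5-fold vs kidney only;
vasculature at 2× brain EC). Designed group means already sum to 10⁶ CPM
via a filler transcript, so the CPM closure after noise is a ~1.0 no-op
and planted fold-changes survive; background genes share one level
across organs with sub-2-fold wobble. The disease table plants
dysfunction genes up in 3–4 of 4 models and background genes in 0–2; an
optional exhaustive 16-pattern sweep covers every up/down combination.
The homolog map drops a configurable suffix of each module (defaults 7
of 162 and 5 of 136); the atlas gene universe contains 147 of the 155
mapped core genes and 128 of the 131 mapped dysfunction genes, so the
raw → mapped → detected chain exercises every attrition step. The
anatomic panel multiplies region mixtures by per-sample vascular factors
(3× in microvascular proliferation), which the microvascular score must
remove.

**What the generator does not emulate:** ambient RNA, empty droplets,
UMI saturation, batch effects beyond mild per-patient mean shifts,
cell-cycle structure, or realistic gene-gene co-expression outside the
planted modules. Passing the recovery tests therefore demonstrates that
the pipeline's logic is correct and calibrated on data matching its
model assumptions — not that it is robust to every artefact of real
droplet data. Conversely the type-I-error calibration (label
permutation) and the exactness of the statistical core are
model-independent checks.

## Problem sizes and runtime

Default sizes were chosen so the full test suite and the acceptance
script each run in a couple of minutes on one CPU: atlas 3,000 × 2,000;
bulk panel ~500 genes × 30 samples; co-expression oracle 500 cells;
approximation calibration 1,000 instances at group sizes 15–25; 20 label
permutations for the calibration check. All are parameters.

## Known limitations

* The in-atlas module coupling (σ = 0.3) is deliberately mild so the
  barrier-state axis does not distort the clustering geometry; the
  quantitative co-expression check runs on a dedicated Gaussian
  generator with exactly specified correlations (±0.5).
* The normal approximations cannot track exact p-values to 0.02 under
  extreme ties at small n (probability atoms exceed the tolerance);
  exact mode covers that regime.
* Patient effects are simulated but not corrected; an integration stage
  is out of scope, and the planted shifts are small enough that recovery
  succeeds without one. On real multi-patient data a batch-integration
  step would be needed before clustering.
* The doublet rule assumes roughly balanced 50:50 heterotypic doublets;
  strongly asymmetric doublets would need a lower
  `min_partner_fraction`.
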