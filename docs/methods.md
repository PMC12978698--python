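# Methods

`ddgnet` is a re-implementation of a cell type-specific network analysis
for outbred mouse single-cell transcriptomes, built to run end to end on
synthetic data with planted ground truth. This note documents the models,
the synthetic-data generator, the numerical choices, and what the passing
test suite does and does not establish about real data.

## The synthetic population

The generator emulates the study design the pipeline targets: bone
marrow-derived stromal cells cultured under osteogenic conditions from a
Diversity Outbred (DO) cohort, with seven mesenchymal clusters on a rooted
tree (MPC → LMP → {OBP → {OB1 → Ocy, OB2}, MALP}) giving three
root-to-leaf lineages. Defaults are a desk scale of 24 mice × 400 cells
(configurable up to the 80 × ~1,700 cohort scale); every experiment below
states the scale it uses.

Counts are negative binomial, `x_gc ~ NB(s_c · exp(η_gc), φ)` with
dispersion φ = 0.4 and lognormal cell size factors (log-sd 0.25, a ±10%
per-batch multiplier). The log-mean η stacks:

- **Cluster markers** (6 genes/cluster, amplitude 1.5 nat): Gaussian bumps
  in pseudotime centered on the cluster's segment of each lineage passing
  through it. Because marker intensity varies smoothly *within* a cluster,
  cells embed along a continuous curve in PCA space and planted pseudotime
  is recoverable, not just cluster identity.
- **Dynamic genes** (30, |log2FC| = 2): a logistic sigmoid in pseudotime
  (width 0.15 segments) centered inside one target cell-type boundary of
  one lineage; cells on branches that diverge before the boundary are
  capped at the branch point. The monotone start-to-end contrast matches
  the start-vs-end test's estimand. Five per module are planted inside the
  module driver's neighborhood (below); the rest are free-standing.
- **Module genes** (3 modules × 30): a linear-Gaussian structural equation
  model on a random preferential-attachment DAG (weights U[0.5, 1.0],
  child noise sd 0.6, roots N(0,1)), drawn **once per mouse** and shared by
  all of that mouse's cells, so per-cluster pseudobulk — the substrate of
  module detection and network learning — carries the DAG correlation
  structure while per-cell NB noise stays independent. Weights are
  positive by default: a *signed* co-expression method can only group
  positively correlated genes into one module, so sign-coherent modules
  are the recoverable planting (mixed signs are available via
  `sem_sign_prob`). The preferential-attachment topology keeps modules
  shallow (most genes within 2–3 steps of a hub), which keeps within-module
  correlations high throughout the module. The planted **driver** is the
  node with the largest radius-3 neighborhood; its planted dynamic genes
  are taken from the driver's strongest direct targets (radius ≤ 2,
  high-degree first) so they remain adjacent to the driver in a sparsely
  learned network and survive degree pruning.
- **cis-eQTL genes** (10, drawn from the noise pool): the founder-dosage
  dot product with a one-founder allelic series of ±1.0 nat (sum-to-zero
  coded), with the TSS placed within 0.5 Mbp of the causal marker.
- **Flagged genes**: small mito/Rpl/Rps sets with elevated baselines
  (~5%/5%/3% of reads); ~3% of cells are generated outside the QC envelope
  (library < 400 or > 6200, or mito > 10%) to exercise the filters.

Genotypes are founder-haplotype mosaics: two haplotypes per chromosome per
mouse, drawn as a Markov chain over 8 founders along 30 uniformly spaced
markers per 100 Mbp chromosome (2 chromosomes, switch probability 0.1 per
step — haplotype blocks of a few tens of Mbp, conservative relative to
real DO genomes). Dosages are founder counts among the two haplotypes and
always sum to 2.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects beyond a library-size multiplier, UMI saturation, linked selection
or realistic DO linkage maps, and any sequence-level process. Passing
recovery tests therefore demonstrate correctness of the pipeline's
statistics under its own assumptions, not robustness to the artifacts of
real scRNA-seq.

## Stage-by-stage notes

**QC.** "Reads" is interpreted as total UMI per cell (the matrix is a UMI
matrix). Cells equal to either library-size bound are retained (the stated
exclusions are strictly "more than"/"less than"). Rpl/Rps/mito flags come
from gene-symbol prefixes (`Rpl`, `Rps`, `mt-`). The fixed 20%/15%
fractions are implemented (the percentile remark that motivated them is
descriptive). Means are rounded half-to-even to 2 decimals.

**VST.** Size factors are median-of-ratios over all-positive rows; per-gene
dispersions are method-of-moments on size-factor-normalized values; the
trend α(μ) = a₁/μ + a₀ is fitted by two passes of gamma-weighted least
squares, with a log-scale constrained fit as fallback and `log2(q+1)` when
a₀ ≤ 0 (logged). The closed-form transform is monotone and is validated by
a variance-flattening property on NB data with a known trend, not by
bit-compatibility with any external tool.

**Quantile normalization.** Columns are mapped onto mean order statistics;
ties receive the mean of the reference values their ranks span
(average-rank interpolation). With ties (pseudobulk zeros) individual
order statistics of different columns can then differ slightly even though
the column distributions coincide; the exact identical-sorted-values
property is asserted on tie-free data and the tie case by near-zero
Kolmogorov distance.

**Trajectories.** Lineages are root-to-leaf paths of the MST over cluster
centroids in 15-component PCA space (log1p-CPM). Pseudotime is arc-length
projection onto the centroid path densified by a chord-length cubic spline
(12 points/segment) — a light-weight stand-in for principal curves that
reduces corner-cutting distortion near segment joints. Cells in clusters
shared by several lineages get per-lineage pseudotime and inverse-squared-
distance weights. Boundaries trim `floor(n(1−c)/2)` cells per tail
(c = 0.78 by default; a 1e-9 epsilon guards the floor against float
error). An optional MPC outlier filter (distance quantile) exists and is
off by default.

**Dynamic genes.** Each gene/lineage is fitted by NB log-link IRLS on a
clamped cubic B-spline basis with 10 knots at pseudotime quantiles, a log
library-size offset and lineage weights; dispersion is method-of-moments
with one refit. A fixed second-difference P-spline penalty (λ = 1,
sandwich covariance) stabilizes the boundary-endpoint contrasts — the
unpenalized 10-knot fit has far too much endpoint variance for useful
power — mirroring the smoothing of NB-GAM smoothers. The start-vs-end
statistic shrinks |Δ| by `l2fc·ln2` before squaring (composite null), so
sub-threshold changes never reach significance and the test is
conservative under the null (measured type-I ≈ 0 at nominal 0.05). The
global test sums the per-lineage thresholded components (independent fits)
with one df per contrast. BH families: one per (boundary, test-type).

**Modules.** Signed adjacency at β = 14, exact TOM, average-linkage
clustering of 1−TOM with a simplified dynamic cut (0.99 height-quantile
cut, recursive splits when both branches hold ≥ 20 genes and the
branch-height gap exceeds 0.02, eigengene merge at r > 0.85), then
iterative refinement with a final enforcement pass so no module re-added
from the residual pool can bypass the kME floors. "Core" kME is the mean
over all members. Eigengenes are first PCs, unit variance, sign-oriented
to positive mean member correlation.

**Bayesian networks.** MMPC with Fisher-z partial-correlation tests
(α = 0.05, conditioning sets ≤ 3 — larger sets are unsupportable at ≤ 80
samples), symmetrized by intersection; hill climbing over add (skeleton
pairs only) / delete / reverse moves on decomposable Gaussian BIC.
Score-equivalent moves (e.g. orienting the first edge of a pair) are exact
ties; a 1e-6 tolerance makes them resolve lexicographically instead of by
float noise, which is what makes collider recovery deterministic.

**DDG calling.** Neighborhoods are radius-3 (undirected by default) on the
degree-pruned network (single pass by default; iterate available), kept if
size > mean + 1 sample SD. The hypergeometric population defaults to
**network** mode: population = pruned-network genes, m = dynamic genes
inside that population, so draws and successes refer to the same urn. The
printed parameterization (m = all dynamic genes for the boundary,
n = retained neighborhoods − m) is preserved verbatim as mode `literal`;
mode `union` (genes of retained neighborhoods) is also available but
degenerates when the retained neighborhoods nearly cover their own union,
as they do in desk-scale networks. The upper tail is evaluated at
q = overlap − 1, so zero overlap gives p = 1 exactly.

**eQTL.** The per-marker model is expression ~ covariates + 8 founder
dosages (one dropped; effects reported sum-to-zero);
LOD = (n/2)·log10(RSS0/RSS1). Scans precompute per-marker orthonormal
dosage bases after residualizing covariates, making the 50-gene ×
permutation threshold a sequence of matrix products. The threshold takes
each gene's 0.95 quantile of genome-wide max LOD, the median over genes
per cluster, and the mean over clusters; autosomes and X are separate when
X markers exist. Kinship is off by default; when enabled, a founder-dosage
GRM with a single variance component (profiled-ML grid over the variance
ratio) decorrelates the scan. The cis rule is same-chromosome TSS distance
≤ 1 Mbp, inclusive.

**Composition and prioritization.** Proportions are arcsine-square-root
transformed; group tests are covariate-adjusted OLS (t for 2 groups, F
above); trait correlations are Pearson with BH per trait. Prioritization
matches DDG symbols to the coloc table case-insensitively (an optional
two-column mapping table covers human-mouse symbol divergence), keeps the
best-scoring tissue per modality (ties alphabetical), and flags genes on a
user-supplied knockout-phenotype list.

## Validation experiments and their scales

The acceptance suite runs each stage against its planted truth at a stated
scale, chosen so the full suite completes in minutes on one CPU:

- trajectory/boundary recovery and module ARI: the default 24-mouse
  population;
- network skeleton F1 and the driver-recovery experiment: n = 500
  SEM samples (the scale at which constraint-based structure learning has
  the power the experiment isolates; at cohort scale MMHC thins dense hub
  regions, a power limit of the learning method rather than of the
  enrichment machinery);
- dynamic-test calibration: 1,000 null + 100 planted genes at 500 cells;
- eQTL power and null FPR: 80 mice, 50 permutation genes × 200
  permutations, 30 simulations per arm.

Two honest limits are worth stating. First, a planted one-founder
allele-substitution effect of 1 residual SD at n = 80 yields expected
LOD ≈ 5.3 (7-df noncentral χ² with λ ≈ 17.5) against a genome-wide 0.95
permutation threshold ≈ 5.5, so detection power is ~0.4–0.55; power ≥ 0.8
at that effect size would require a threshold whose genome-wide null
false-positive rate far exceeds 0.10. The package reports both numbers as
measured. Second, full end-to-end driver prioritization at desk scale is
limited by the same structure-learning power compounded with BH across all
neighborhoods of a cluster; the pipeline's end-to-end run is therefore
validated structurally (lineage topology, boundary coverage, dynamic-gene
recall, determinism) while driver recovery is validated in the dedicated
experiment above.
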