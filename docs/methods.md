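# Methods

This note documents the models, parameter choices and numerical decisions
behind `metacomp`, and what the synthetic benchmark does and does not
establish about real data.

## Preprocessing

Counts are depth-normalized to 10,000 per cell and transformed with the
natural log1p. Cells are filtered on library size ≥ 1000, detected genes
≥ 500 and mitochondrial read fraction ≤ 5% ("MT-" prefix,
case-insensitive, configurable regex); thresholds are inclusive, which
makes boundary behavior testable. For TPM/FPKM-like inputs only the log
transform and the detected-gene filter apply (library size and
mitochondrial content are not meaningful after within-cell normalization);
already log-normalized input passes through. Gene universes are harmonized
across cohorts by strict intersection by default, because component
correlation requires a common axis and zero-filling absent genes would
bias correlations toward zero; union with zero-fill is available via
`min_fraction < 1`.

## Decomposition

Each cohort is decomposed with FastICA (scikit-learn): logcosh contrast,
whitening to unit variance, tolerance 1e-7, at most 1000 iterations. The
tight tolerance is deliberate: it makes repeated runs on identical data
land on the same fixed point, which underpins the duplication-stability
guarantee. A non-convergent run is retried once with seed+1 and otherwise
accepted with `converged=False` — a flagged approximate decomposition is
more useful than an error deep inside a multi-cohort loop. k = 100 by
default (comfortably above the number of distinct cell states expected in
a tissue); k is clipped to min(cells, genes) − 1 with a warning on small
matrices. Genes with zero variance within a cohort are removed before ICA
and re-inserted as exact zero z-weights, so all components live on the
harmonized gene universe; the unit-SD property of a component therefore
holds over the genes that entered the decomposition.

z-weights are the full z-score (center and scale, population SD) of a
component's gene loadings. ICA loadings are near zero-mean anyway, so
centering is almost a no-op, but it makes the |z| ≥ 2 significance cutoff
exactly a two-standard-deviation statement. Sign alignment flips a
component when its sample skewness (third standardized moment) is
negative; the skewness-test statistic is recorded for reporting. The sign
of the test statistic equals the sign of the sample skewness, so the
simpler quantity decides.

The run seed is applied uniformly to every cohort's decomposition.
Identical inputs then decompose identically — which is what makes
"discovery on N copies of one dataset returns that dataset's own
components" hold exactly — and distinct cohorts are still decomposed
independently because their data differ.

NMF (nndsvda initialization) is available as an alternative decomposition
for benchmarking; its components pass through the same
z-normalization/alignment path so both methods are compared on equal
footing.

## Meta-component calling

Similarity between pooled components is Pearson correlation of z-weight
vectors. On centered unit-SD vectors Pearson correlation and cosine
similarity nearly coincide; Pearson is used throughout because the 0.3
reproducibility cutoff is stated as a correlation. A component is
reproducible if it correlates at ≥ 0.3 with a component of a *different*
cohort (the cross-cohort requirement is the point of the filter; a flag
relaxes it to any other component).

Clustering runs on a thresholded weighted graph — edges between component
pairs with r ≥ 0.3, edge weight r — the minimal construction consistent
with the reproducibility filter. Communities are found with the Leiden
algorithm (`leidenalg`, RBConfiguration partition, 2 iterations, seeded),
a refinement of the Louvain modularity family with an explicit resolution
parameter and reproducible output. Clusters with fewer than 5 members are
discarded; survivors are relabeled by descending size, so MeC-0 is always
the most recurrent program. MeC z-weights are the arithmetic mean of the
member vectors and are *not* re-standardized: averages of unit-SD vectors
keep the z-weight scale, and the significance cutoff 2 applies to the
averaged values.

Resolution selection scans a grid (0.25–3.0, step 0.25 by default). For
each grid point it computes the number of retained clusters and the
silhouette score of the clustered components only (distance 1 − r);
unclustered components are excluded because discarded singletons say
nothing about partition quality. Among grid points whose silhouette is
within 5% of the maximum, the one with the most retained clusters wins;
ties break toward the smaller resolution. This formalizes "jointly
optimize cohesion and granularity" with a single documented rule.

Leave-one-out robustness re-runs discovery with each cohort held out and
reports the mean of the row-wise and column-wise maxima of the
correlation matrix between held-out and full-data MeCs, plus the MeC
counts.

## Annotation

Projection uses only a MeC's significant genes (z ≥ 2): the score is the
dot product of log expression with the z-weights over those genes, with
absent genes contributing zero (an option adds the negative tail with its
negative weights). Scores are z-scaled per MeC across all cells with the
sample SD (ddof = 1); no rank-based transform is applied. Over-clustering
is the standard scanpy pipeline — 2000 highly-variable genes, scaling,
PCA (≤ 50 components, arpack), 15-NN graph, Leiden at resolution 8 — all
seeded; an optional hook can transform the PCA embedding before graph
construction (e.g. an external batch-correction step). A cluster's
enriched MeCs are those with mean scaled score ≥ 2; the top one names the
cluster's state, ties breaking toward the lower MeC id (the larger
discovery cluster); clusters with none are "Unassigned".

## Differential testing

Within each cluster, each enriched MeC is compared between exactly two
conditions with a two-sided Welch t-test by default (the unequal-variance
form needs no pooled-variance assumption; Wilcoxon rank-sum is the
alternative). Effect size is mean(condition 2) − mean(condition 1).
Clusters missing a condition or with fewer than 10 cells in either are
skipped. Benjamini–Hochberg adjustment is applied across all emitted
records and reported alongside the raw p, so either convention can be
plotted. Constant scores yield p = 1 rather than NaN. The mean score in
the favored condition is emitted per record (the quantity a
significance–effect scatter sizes its dots by).

## TF prioritization

Inputs are a TF × MeC table of −log₁₀ p regulatory-potential
significances (computed upstream by any ChIP-seq-based tool) and a TF
catalog; the module never runs such a tool itself, which keeps it
dependency-free and testable on synthetic tables. Per MeC and TF:
jointly significant means z-weight ≥ 2 and −log₁₀ p ≥ 2; the aggregated
rank is the arithmetic mean of the z-weight rank *among all genes* and
the regulatory-score rank among scored TFs, with rank ≤ 40 marking the
strongest joint candidates; the expression-only and binding-only flags
take the top 10 of the respective ranking among catalog TFs, excluding
jointly significant TFs (they are "only" lists). Competition ranking
(ties share the smallest rank) keeps the flags deterministic. TFs absent
from the MeC gene universe get z-weight 0 with a warning.

## Synthetic multi-cohort benchmark

The generator plants 14 programs — 13 mutually exclusive cell-identity
programs and 1 activity program that switches on across cell types — as
multiplicative factors (uniform in [2, 6]) on disjoint 50-gene blocks of a
1000-gene universe. Counts follow a hierarchical gamma–Poisson model:
per-gene baseline relative means are lognormal(μ = 0.5, σ = 1); a cell's
mean vector is the baseline times the factors of its programs; a
gamma multiplier with CV 0.2 adds biological overdispersion; library
sizes are lognormal(μ = 9, σ = 0.3) (~8100 counts median); counts are
Poisson at depth × normalized relative mean. Each cohort carries a random
subset of 5–13 identity programs, mirroring the fact that real cohorts do
not contain every cell type, and the activity program with probability
0.5; in a carrier cohort each cell switches it on with probability 0.5 at
a per-cell strength uniform in [0.5, 1] (factors interpolated toward 1),
mimicking a graded signaling response. All parameter values are fixed
defaults of the generator; everything is driven by a single seed. The
standard fixture is 20 cohorts × 500 cells with per-cohort decomposition
at k = 20.

Recovery is evaluated by Pearson correlation between predicted MeCs and
the z-scored log factor vectors of the true programs, with a one-to-one
assignment maximizing total correlation (Hungarian algorithm; a greedy
matcher is available for comparison). The Hungarian choice makes the
report deterministic and order-free. Mutual independence of a predicted
set is the mean absolute off-diagonal correlation. Cross-cluster entropy
of a signature is the entropy (natural log) of the per-cluster mean
positive-part scores normalized to a distribution over clusters; an
all-zero signature reports the maximal entropy log(n_clusters). The
positive-part-mean construction is this package's concrete definition of
the metric.

What the simulator does *not* emulate: within-cohort batch effects,
doublets, ambient RNA, zero inflation beyond the gamma–Poisson, partially
overlapping programs, or realistic gene-gene correlation beyond the
planted blocks. Passing the benchmark therefore shows that the pipeline
recovers recurring linear expression programs from independent noisy
cohorts and that its bookkeeping (filtering, clustering, matching,
scoring) is correct — not that ICA will resolve every state in real
tissue.

## Problem sizes and runtime

The test suite and the acceptance script run on desk-scale fixtures
chosen to keep the full suite in a few minutes on one CPU: the standard
20 × 500-cell fixture for recovery claims (5 seeds for the stochastic
majority-vote properties), a 6 × 150-cell fixture for unit-level
pipeline tests, 1000 repetitions for the type-I-error calibration, and
6 × 300-cell cohorts for the leave-one-out analysis at k = 15. Corpus-
scale quantities reported for the motivating application (tens of
millions of cells, 86 tumor MeCs, 6623 feature genes) require the
original multi-study corpus and are out of scope; the package asserts
the corresponding *properties* (duplication stability, leave-one-out
correlation near 1, recovery improving with cohort count) on synthetic
data instead.

## Known limitations

* Pure Smart-seq (TPM) cohorts are QC-filtered only on detected genes;
  whether library-size filters should apply to normalized units is
  genuinely ambiguous and the choice is documented above.
* The resolution-selection rule is one defensible formalization of a
  joint optimum; a different rule can shift the MeC count on pools
  without clear cluster structure.
* MeC membership metadata is not preserved in the flat z-weight TSV, so
  MeCs reloaded from disk (`tables.read_mecs`) carry empty member lists.
* The similarity graph is dense in construction (O(n²) in pooled
  components); fine for thousands of components, not tuned for far more.
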