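# metacomp

Meta-component discovery for multi-cohort single-cell RNA-seq.

Single-cell atlases of complex tissues — the tumor microenvironment being
the motivating case — are assembled from many independent cohorts, and the
standard route to shared cell-state definitions (batch integration,
clustering, manual marker curation) scales poorly and varies between
studies. `metacomp` takes the *integration-after-decomposition* route:
each cohort is decomposed independently into interpretable gene-expression
components, and only the components that recur across cohorts are merged
into consensus signatures, so no joint embedding of millions of cells is
ever required and cohort-specific batch structure never mixes.

The package is for computational biologists who want to (1) learn
reproducible transcriptional programs from a collection of scRNA-seq count
matrices, (2) use those programs to annotate cell states in new data, (3)
test program activity between conditions (e.g. pre/post immunotherapy),
and (4) shortlist candidate transcription-factor regulators per program.
A fully seeded multi-cohort count simulator with planted ground-truth
programs makes every stage testable offline.

## Method

For each cohort *d* with log-normalized expression matrix
**X**<sub>d</sub> (cells × genes), FastICA (logcosh contrast, whitening)
factorizes

&nbsp;&nbsp;&nbsp;&nbsp;**X**<sub>d</sub> ≈ **A**<sub>d</sub> **S**<sub>d</sub>,

where the rows of **S**<sub>d</sub> (k = 100 by default) are independent
components in gene space. Each component is made comparable across cohorts
by a z-score transform of its gene loadings (z-weights, unit SD) and a
sign flip whenever the weight distribution is left-skewed, so the
representative genes always sit on the positive tail. Genes with
|z| ≥ 2 are the component's significant contributors.

Components from all cohorts are pooled and a component is kept as
*reproducible* if its Pearson correlation with some component of another
cohort is ≥ 0.3. The reproducible components form a weighted graph
(edges at r ≥ 0.3) clustered by resolution-parameterized community
detection; clusters with ≥ 5 members become **meta-components (MeCs)**,
each the arithmetic mean of its members' z-weight vectors, ordered by
cluster size. The resolution is chosen automatically by jointly optimizing
the silhouette of the retained clusters (distance 1 − r) and the number of
reproducible clusters.

Downstream:

* **Annotation** — a query cell's score for a MeC is the dot product of
  its log expression with the MeC z-weights over the significant genes
  (z ≥ 2); scores are z-scaled across cells, cells are deliberately
  over-clustered (resolution 8), and each cluster is labeled by its
  top-enriched MeC (mean scaled score ≥ 2).
* **Differential signatures** — within each annotated cluster, every
  enriched MeC is compared between two conditions by a two-sided Welch
  t-test (or Wilcoxon); the effect size is the difference of condition
  means, with Benjamini–Hochberg adjusted p-values alongside the raw ones.
* **TF prioritization** — per MeC, each transcription factor combines its
  expression z-weight with a precomputed regulatory-potential significance
  (−log₁₀ p); TFs are flagged as jointly significant (both ≥ 2, optionally
  within aggregated rank 40), expression-only (top 10 by z-weight) or
  binding-only (top 10 by regulatory score).
* **Benchmark** — the simulator plants 13 cell-identity programs plus one
  cross-cutting activity program (14 total) into gamma–Poisson counts over
  any number of cohorts; recovery is scored by Pearson correlation between
  predicted and true programs under one-to-one Hungarian matching.

## Worked example

```bash
python examples/01_discover_mecs.py
```

simulates six cohorts sharing 7 planted programs and runs the full
discovery stage:

```
pooled components:        60
reproducible components:  30
chosen resolution:        2.5
meta-components found:    7
feature genes (|z|>=2):   179
  MeC-0: cluster of 5 components; top genes g0052, g0045, g0037, g0038, g0163
  MeC-1: cluster of 5 components; top genes g0158, g0097, g0171, g0156, g0091
  MeC-2: cluster of 4 components; top genes g0067, g0089, g0087, g0085, g0083
```

Six cohorts × 10 components give 60 pooled components; half recur in
another cohort at r ≥ 0.3 and survive the reproducibility filter; they
cluster into 7 meta-components — one per planted program — whose top genes
are drawn from the correct planted gene blocks. `examples/05_benchmark_recovery.py`
quantifies recovery against the ground truth:

```
ICA recovery (fraction of 14 planted programs matched at r >= 0.7):
   5 cohorts: recovered 0.21, mean |pairwise r| 0.038
   8 cohorts: recovered 0.64, mean |pairwise r| 0.076
  12 cohorts: recovered 0.93, mean |pairwise r| 0.069
NMF at 12 cohorts: recovered 1.00, mean |pairwise r| 0.241
```

Recovery improves with cohort count (a program must recur in ≥ 5 cohorts
to survive), and the ICA-derived programs are markedly more mutually
independent than NMF-derived ones. The other examples cover annotation,
differential testing and TF ranking; each prints a short explanation of
its numbers.

The same pipeline is exposed as a CLI for shell use:

```bash
metacomp simulate --out sim/ --n-datasets 6 --cells 300 --seed 0
metacomp discover --input sim/cohort00 ... --format mtx_triplet \
    --k 20 --seed 0 --out run/
metacomp annotate --query new_data.tsv --mecs run/mec_weights.tsv \
    --resolution 8 --seed 0 --out ann/
```

Every stage writes a JSON manifest (parameters, input hashes, seed) that
suffices to re-run it exactly.

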