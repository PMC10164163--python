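"""Projecting query cells onto meta-components and calling cell states.

A query log-expression matrix is projected onto each MeC by a dot product
over that MeC's significant genes (z-weight >= 2), the raw scores are
z-scaled per MeC across all cells, the cells are intentionally
over-clustered (default resolution 8) so fine states remain separable, and
each cluster is labeled by its most enriched MeC (mean scaled score >= 2).
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional, Sequence

import numpy as np

from .containers import (
    ClusterEnrichment,
    LogExpressionMatrix,
    MeC,
    MeCScoreMatrix,
)

ENRICHMENT_CUTOFF = 2.0
OVERCLUSTER_RESOLUTION = 8.0
UNASSIGNED_LABEL = "Unassigned"


def project_cells(
    query: LogExpressionMatrix,
    mecs: Sequence[MeC],
    include_negative: bool = False,
) -> MeCScoreMatrix:
    """Raw per-cell MeC scores: expression . z-weights over significant genes.

    Only genes with z-weight >= 2 in a MeC contribute (optionally also the
    negative tail, z <= -2, with their negative weights). Genes absent from
    the query contribute 0; a MeC with no significant gene present in the
    query gets an all-zero column with a warning.
    """
    if not len(mecs):
        raise ValueError("no MeCs to project onto")
    gene_index = {g: j for j, g in enumerate(query.gene_ids)}
    raw = np.zeros((query.n_cells, len(mecs)))
    genes_used: dict[str, int] = {}
    total_sig = 0
    total_found = 0
    for j, mec in enumerate(mecs):
        mask = mec.zweights >= mec.SIGNIFICANT_Z
        if include_negative:
            mask |= mec.zweights <= -mec.SIGNIFICANT_Z
        sig_genes = mec.gene_ids[mask]
        sig_weights = mec.zweights[mask]
        cols, weights = [], []
        for g, w in zip(sig_genes, sig_weights):
            if g in gene_index:
                cols.append(gene_index[g])
                weights.append(w)
        total_sig += len(sig_genes)
        total_found += len(cols)
        genes_used[mec.name] = len(cols)
        if not cols:
            warnings.warn(
                f"{mec.name}: no significant gene present in query; scores set "
                "to 0", UserWarning, stacklevel=2,
            )
            continue
        raw[:, j] = query.values[:, cols] @ np.asarray(weights)
    if total_sig and total_found == 0:
        raise ValueError("query shares no gene symbols with the MeC table")
    if total_sig and total_found / total_sig < 0.5:
        warnings.warn(
            f"only {total_found}/{total_sig} significant MeC genes found in the "
            "query; check gene-symbol conventions",
            UserWarning, stacklevel=2,
        )
    return MeCScoreMatrix(
        scores=raw.copy(),
        raw_scores=raw,
        cell_ids=query.cell_ids.copy(),
        mec_ids=[m.name for m in mecs],
        genes_used_per_mec=genes_used,
    )


def scale_scores(raw: MeCScoreMatrix) -> MeCScoreMatrix:
    """z-scale each MeC's scores across all cells (sample SD); a
    zero-variance column becomes all zeros."""
    if raw.n_cells < 2:
        raise ValueError("scaling needs at least 2 cells")
    x = raw.raw_scores
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    scaled = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return MeCScoreMatrix(
        scores=scaled,
        raw_scores=raw.raw_scores,
        cell_ids=raw.cell_ids,
        mec_ids=raw.mec_ids,
        genes_used_per_mec=raw.genes_used_per_mec,
        cluster_labels=raw.cluster_labels,
    )


def overcluster(
    query: LogExpressionMatrix,
    resolution: float = OVERCLUSTER_RESOLUTION,
    seed: int = 0,
    n_top_genes: int = 2000,
    n_pcs: int = 50,
    embedding_hook: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """High-resolution graph clustering of the query cells.

    Standard single-cell pipeline: highly-variable-gene selection, PCA,
    kNN graph, Leiden communities at the given (deliberately high)
    resolution. ``embedding_hook`` may transform the PCA embedding before
    graph construction (e.g. an external batch-correction step).
    """
    import scanpy as sc
    import anndata as ad

    adata = ad.AnnData(
        X=query.values.copy(),
        obs={"cell": list(query.cell_ids)},
        var={"gene": list(query.gene_ids)},
    )
    adata.obs_names = [str(c) for c in query.cell_ids]
    adata.var_names = [str(g) for g in query.gene_ids]
    n_top = min(n_top_genes, query.n_genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
        sc.pp.scale(adata, max_value=10)
        n_comps = int(min(n_pcs, adata.n_obs - 1, adata.n_vars - 1))
        sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
        if embedding_hook is not None:
            adata.obsm["X_pca"] = np.asarray(embedding_hook(adata.obsm["X_pca"]))
        sc.pp.neighbors(adata, n_neighbors=15, random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=float(resolution),
            random_state=seed,
            key_added="overcluster",
            flavor="leidenalg",
        )
    return adata.obs["overcluster"].to_numpy(dtype=object)


def enrich_clusters(
    scores: MeCScoreMatrix,
    labels: Sequence[str],
    cutoff: float = ENRICHMENT_CUTOFF,
) -> list[ClusterEnrichment]:
    """Per-cluster mean scaled score per MeC; MeCs passing the cutoff are the
    cluster's enriched set and the top one names its state."""
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != scores.n_cells:
        raise ValueError("labels must cover all cells")
    out = []
    for cluster in sorted(set(labels), key=str):
        mean = scores.scores[labels == cluster].mean(axis=0)
        # deterministic ordering: descending score, ties to lower mec index
        order = sorted(range(len(mean)), key=lambda j: (-mean[j], j))
        enriched = [
            (scores.mec_ids[j], float(mean[j])) for j in order if mean[j] >= cutoff
        ]
        top = enriched[0][0] if enriched else None
        out.append(
            ClusterEnrichment(
                cluster_id=str(cluster),
                enriched_mecs=enriched,
                top_mec=top,
                state_label=top if top is not None else UNASSIGNED_LABEL,
            )
        )
    return out


def annotate(
    query: LogExpressionMatrix,
    mecs: Sequence[MeC],
    resolution: float = OVERCLUSTER_RESOLUTION,
    seed: int = 0,
    cutoff: float = ENRICHMENT_CUTOFF,
    embedding_hook: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> tuple[MeCScoreMatrix, list[ClusterEnrichment]]:
    """Full annotation: project, scale, over-cluster, call enriched states."""
    scored = scale_scores(project_cells(query, mecs))
    labels = overcluster(
        query, resolution=resolution, seed=seed, embedding_hook=embedding_hook
    )
    scored.cluster_labels = labels
    enrichments = enrich_clusters(scored, labels, cutoff=cutoff)
    return scored, enrichments
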