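"""Meta-component (MeC) discovery.

Components from all datasets are pooled on a shared gene axis, filtered to
those reproducible across cohorts (Pearson r >= 0.3 with a component from
another dataset), clustered on a thresholded weighted similarity graph with
resolution-parameterized community detection, and averaged per cluster into
meta-component z-weight profiles. Cluster resolution can be chosen
automatically by jointly optimizing the silhouette of the retained clusters
and the number of reproducible clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph
import leidenalg
import numpy as np
from sklearn.metrics import silhouette_score

from .containers import (
    Component,
    ComponentPool,
    DecompositionResult,
    LogExpressionMatrix,
    MeC,
    ResolutionScan,
)
from . import decomposition

MIN_CORR_DEFAULT = 0.3
MIN_CLUSTER_SIZE_DEFAULT = 5
# Covers the resolution range that is useful on pools of tens to ~1000
# components; step 0.25.
RESOLUTION_GRID_DEFAULT = tuple(np.arange(0.25, 3.01, 0.25).round(2))


def pool_and_correlate(results: Sequence[DecompositionResult]) -> ComponentPool:
    """Pool components from >=2 datasets and compute pairwise Pearson r."""
    if len({r.dataset_id for r in results}) < 2:
        raise ValueError("component pooling requires components from >=2 datasets")
    gene_ids = results[0].gene_ids
    for r in results[1:]:
        if not np.array_equal(r.gene_ids, gene_ids):
            raise ValueError(
                "all decompositions must share one gene axis; run "
                "harmonize_genes before decomposing"
            )
    components = [c for r in results for c in r.components]
    Z = np.vstack([c.zweights for c in components])
    with np.errstate(invalid="ignore"):
        sim = np.corrcoef(Z)
    sim = np.nan_to_num(sim, nan=0.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2
    return ComponentPool(components=components, gene_ids=gene_ids, similarity=sim)


def filter_reproducible(
    pool: ComponentPool,
    min_corr: float = MIN_CORR_DEFAULT,
    cross_dataset: bool = True,
) -> ComponentPool:
    """Keep components correlated (r >= min_corr) with at least one other
    component — from a different dataset when ``cross_dataset`` is set."""
    n = pool.n_components
    sim = pool.similarity.copy()
    np.fill_diagonal(sim, -np.inf)
    if cross_dataset:
        ds = pool.dataset_ids
        same = ds[:, None] == ds[None, :]
        sim[same] = -np.inf
    best_partner = sim.max(axis=1)
    keep = best_partner >= min_corr
    if not keep.any():
        raise ValueError(
            "no reproducible components: max observed cross-component "
            f"correlation {best_partner.max():.4f} < min_corr={min_corr}"
        )
    idx = np.flatnonzero(keep)
    return ComponentPool(
        components=[pool.components[i] for i in idx],
        gene_ids=pool.gene_ids,
        similarity=pool.similarity[np.ix_(idx, idx)],
    )


def _build_graph(similarity: np.ndarray, edge_threshold: float) -> igraph.Graph:
    """Weighted graph with edges between component pairs at r >= threshold."""
    n = similarity.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = similarity[iu, ju] >= edge_threshold
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = similarity[iu, ju][mask].tolist()
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def _relabel_by_size(labels: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """Discard clusters below the size floor; relabel survivors 0..m-1 by
    descending size (ties by smallest original label). Discarded -> -1."""
    out = np.full(labels.shape, -1, dtype=int)
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(
        (int(u) for u, c in zip(uniq, counts) if c >= min_cluster_size),
        key=lambda u: (-int(counts[uniq == u][0]), u),
    )
    for new, old in enumerate(order):
        out[labels == old] = new
    return out


def cluster_components(
    pool: ComponentPool,
    resolution: float,
    min_cluster_size: int = MIN_CLUSTER_SIZE_DEFAULT,
    seed: int = 0,
    edge_threshold: float = MIN_CORR_DEFAULT,
) -> np.ndarray:
    """Community detection on the component similarity graph.

    Returns one label per pooled component; clusters smaller than
    ``min_cluster_size`` are discarded (label -1). Labels are ordered by
    descending cluster size. Deterministic for a fixed seed.
    """
    if pool.n_components < min_cluster_size:
        warnings.warn(
            f"pool of {pool.n_components} components is smaller than "
            f"min_cluster_size={min_cluster_size}; nothing clusterable",
            UserWarning,
            stacklevel=2,
        )
        return np.full(pool.n_components, -1, dtype=int)
    g = _build_graph(pool.similarity, edge_threshold)
    if g.ecount() == 0:
        warnings.warn("no component pair passes the edge threshold", UserWarning,
                      stacklevel=2)
        return np.full(pool.n_components, -1, dtype=int)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=float(resolution),
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    out = _relabel_by_size(labels, min_cluster_size)
    if (out == -1).all():
        warnings.warn("no cluster passes the size filter", UserWarning, stacklevel=2)
    return out


def select_resolution(
    pool: ComponentPool,
    grid: Sequence[float] = RESOLUTION_GRID_DEFAULT,
    min_cluster_size: int = MIN_CLUSTER_SIZE_DEFAULT,
    seed: int = 0,
    edge_threshold: float = MIN_CORR_DEFAULT,
) -> ResolutionScan:
    """Scan a resolution grid, scoring each point by the silhouette of the
    retained clusters (distance 1 - r) and the retained-cluster count.

    The chosen resolution maximizes the cluster count among grid points
    whose silhouette is within 5% of the maximum; ties break toward the
    smaller resolution.
    """
    if len(grid) == 0:
        raise ValueError("resolution grid must be non-empty")
    n_clusters, sils = [], []
    for res in grid:
        labels = cluster_components(
            pool, res, min_cluster_size=min_cluster_size, seed=seed,
            edge_threshold=edge_threshold,
        )
        clustered = labels >= 0
        k = int(labels[clustered].max()) + 1 if clustered.any() else 0
        n_clusters.append(k)
        if k >= 2 and clustered.sum() > k:
            dist = 1.0 - pool.similarity[np.ix_(
                np.flatnonzero(clustered), np.flatnonzero(clustered))]
            np.fill_diagonal(dist, 0.0)
            dist = np.clip(dist, 0.0, None)
            sils.append(float(silhouette_score(dist, labels[clustered],
                                               metric="precomputed")))
        else:
            sils.append(float("-inf") if k == 0 else 0.0)
    sils_arr = np.asarray(sils)
    max_sil = sils_arr.max()
    if np.isfinite(max_sil):
        cutoff = max_sil - 0.05 * abs(max_sil)
        candidates = [i for i, s in enumerate(sils) if s >= cutoff]
    else:
        candidates = list(range(len(grid)))
    best = min(candidates, key=lambda i: (-n_clusters[i], grid[i]))
    return ResolutionScan(
        grid=[float(r) for r in grid],
        n_clusters=n_clusters,
        silhouette=[float(s) for s in sils],
        chosen_resolution=float(grid[best]),
    )


def call_mecs(pool: ComponentPool, assignment: np.ndarray) -> list[MeC]:
    """Average member z-weights per retained cluster into MeC profiles,
    ordered by descending cluster size (MeC-0 is the largest cluster)."""
    assignment = np.asarray(assignment)
    mecs = []
    labels = [int(l) for l in np.unique(assignment) if l >= 0]
    for new_id, label in enumerate(labels):
        idx = np.flatnonzero(assignment == label)
        Z = np.vstack([pool.components[i].zweights for i in idx])
        members = [
            (pool.components[i].dataset_id, pool.components[i].component_index)
            for i in idx
        ]
        mecs.append(
            MeC(
                mec_id=new_id,
                zweights=Z.mean(axis=0),
                gene_ids=pool.gene_ids,
                member_components=members,
                cluster_size=len(members),
            )
        )
    return mecs


def select_feature_genes(pool: ComponentPool, cutoff: float = 2.0) -> np.ndarray:
    """Genes with |z-weight| >= cutoff in at least one pooled component."""
    Z = pool.zweight_matrix()
    keep = (np.abs(Z) >= cutoff).any(axis=0)
    return pool.gene_ids[keep]


@dataclass
class DiscoveryRun:
    """Everything produced by one end-to-end MeC discovery."""

    mecs: list[MeC]
    pool: ComponentPool
    reproducible_pool: ComponentPool
    assignment: np.ndarray
    resolution: float
    scan: Optional[ResolutionScan]
    decompositions: list[DecompositionResult] = field(default_factory=list)

    @property
    def feature_genes(self) -> np.ndarray:
        return select_feature_genes(self.reproducible_pool)


def discover_from_decompositions(
    results: Sequence[DecompositionResult],
    min_corr: float = MIN_CORR_DEFAULT,
    min_cluster_size: int = MIN_CLUSTER_SIZE_DEFAULT,
    resolution: float | str = "auto",
    resolution_grid: Sequence[float] = RESOLUTION_GRID_DEFAULT,
    cross_dataset: bool = True,
    seed: int = 0,
) -> DiscoveryRun:
    """Pool -> reproducibility filter -> cluster -> average, from
    precomputed per-dataset decompositions."""
    pool = pool_and_correlate(results)
    repro = filter_reproducible(pool, min_corr=min_corr, cross_dataset=cross_dataset)
    scan = None
    if resolution == "auto":
        scan = select_resolution(
            repro, grid=resolution_grid, min_cluster_size=min_cluster_size,
            seed=seed, edge_threshold=min_corr,
        )
        res = scan.chosen_resolution
    else:
        res = float(resolution)
    assignment = cluster_components(
        repro, res, min_cluster_size=min_cluster_size, seed=seed,
        edge_threshold=min_corr,
    )
    mecs = call_mecs(repro, assignment)
    return DiscoveryRun(
        mecs=mecs,
        pool=pool,
        reproducible_pool=repro,
        assignment=assignment,
        resolution=res,
        scan=scan,
        decompositions=list(results),
    )


def discover_mecs(
    datasets: Sequence[LogExpressionMatrix],
    k: int = decomposition.DEFAULT_K,
    seed: int = 0,
    method: str = "ica",
    min_corr: float = MIN_CORR_DEFAULT,
    min_cluster_size: int = MIN_CLUSTER_SIZE_DEFAULT,
    resolution: float | str = "auto",
    resolution_grid: Sequence[float] = RESOLUTION_GRID_DEFAULT,
    cross_dataset: bool = True,
) -> DiscoveryRun:
    """End-to-end MeC discovery from harmonized per-dataset log matrices.

    The run seed is applied uniformly to every dataset's decomposition, so
    identical datasets decompose identically and the whole run is
    reproducible from (data, k, seed).
    """
    results = [
        decomposition.decompose_dataset(d, k=k, seed=seed, method=method)
        for d in datasets
    ]
    return discover_from_decompositions(
        results,
        min_corr=min_corr,
        min_cluster_size=min_cluster_size,
        resolution=resolution,
        resolution_grid=resolution_grid,
        cross_dataset=cross_dataset,
        seed=seed,
    )


def mec_correlation(a: Sequence[MeC], b: Sequence[MeC]) -> np.ndarray:
    """Pearson correlation matrix between two MeC sets on a shared gene axis."""
    if not len(a) or not len(b):
        raise ValueError("both MeC sets must be non-empty")
    if not np.array_equal(a[0].gene_ids, b[0].gene_ids):
        raise ValueError("MeC sets live on different gene axes")
    Za = np.vstack([m.zweights for m in a])
    Zb = np.vstack([m.zweights for m in b])
    full = np.corrcoef(np.vstack([Za, Zb]))
    return full[: len(a), len(a):]


def mean_max_correlation(corr: np.ndarray) -> float:
    """Mean over the union of row-wise and column-wise maxima of a
    correlation matrix — the robustness metric for leave-one-out testing."""
    return float(np.concatenate([corr.max(axis=1), corr.max(axis=0)]).mean())


def leave_one_out(
    datasets: Sequence[LogExpressionMatrix],
    k: int = decomposition.DEFAULT_K,
    seed: int = 0,
    **discovery_params,
) -> dict:
    """Robustness check: re-discover MeCs with each dataset held out and
    compare with the full-data MeCs by mean-max correlation."""
    if len(datasets) < 3:
        raise ValueError("leave-one-out needs >=3 datasets")
    results = [
        decomposition.decompose_dataset(d, k=k, seed=seed) for d in datasets
    ]
    full = discover_from_decompositions(results, seed=seed, **discovery_params)
    per_holdout, counts = [], []
    for i in range(len(datasets)):
        rest = results[:i] + results[i + 1:]
        run = discover_from_decompositions(rest, seed=seed, **discovery_params)
        counts.append(len(run.mecs))
        if run.mecs and full.mecs:
            corr = mec_correlation(run.mecs, full.mecs)
            per_holdout.append(mean_max_correlation(corr))
        else:
            per_holdout.append(float("nan"))
    return {
        "mean_max_correlation": float(np.nanmean(per_holdout)),
        "per_holdout_correlation": per_holdout,
        "mec_counts": counts,
        "full_mec_count": len(full.mecs),
    }
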