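"""In-memory containers shared across the pipeline.

All expression matrices are dense cells x genes ``float64`` arrays; at the
scale this package targets (tens of cohorts of a few hundred to a few
thousand cells each) dense storage is simpler and fast enough, and every
downstream step (ICA, correlation, projection) densifies anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

Units = ("counts", "tpm_fpkm", "lognorm")


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


@dataclass
class RawCountMatrix:
    """One dataset's expression matrix before normalization.

    ``values`` is cells x genes. ``units`` records whether the entries are
    raw counts, TPM/FPKM-like normalized units, or already log-normalized.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    dataset_id: str
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.units not in Units:
            raise ValueError(f"unknown units {self.units!r}; expected one of {Units}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError(f"duplicate cell ids in dataset {self.dataset_id!r}")
        if self.units == "counts" and self.values.size and self.values.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LogExpressionMatrix:
    """Cells x genes log-scale expression for one dataset, post-QC."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    dataset_id: str
    qc_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("shape mismatch between values and axis labels")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("log expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Component:
    """One independent component as a gene z-weight vector.

    ``zweights`` has unit standard deviation over the genes that entered the
    decomposition (genes dropped for zero variance re-enter as exact zeros).
    The sign is aligned so the weight distribution has non-negative skewness,
    making the largest positive weights the representative genes.
    """

    zweights: np.ndarray
    dataset_id: str
    component_index: int
    skew_stat: float = 0.0
    flipped: bool = False

    def __post_init__(self) -> None:
        self.zweights = np.asarray(self.zweights, dtype=np.float64)


@dataclass
class DecompositionResult:
    components: list[Component]
    cell_loadings: np.ndarray  # cells x k
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    dataset_id: str
    k: int
    seed: int
    converged: bool = True

    def zweight_matrix(self) -> np.ndarray:
        """k x genes matrix of aligned z-weights."""
        return np.vstack([c.zweights for c in self.components])


@dataclass
class ComponentPool:
    """Components pooled across datasets on a shared gene axis, with their
    pairwise Pearson correlation matrix."""

    components: list[Component]
    gene_ids: np.ndarray
    similarity: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.components)
        if self.similarity.shape != (n, n):
            raise ValueError("similarity matrix shape does not match pool size")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def dataset_ids(self) -> np.ndarray:
        return np.asarray([c.dataset_id for c in self.components], dtype=object)

    def zweight_matrix(self) -> np.ndarray:
        return np.vstack([c.zweights for c in self.components])


@dataclass
class MeC:
    """A meta-component: the averaged z-weight profile of one cluster of
    components reproducible across cohorts."""

    mec_id: int
    zweights: np.ndarray
    gene_ids: np.ndarray
    member_components: list[tuple[str, int]]
    cluster_size: int

    SIGNIFICANT_Z: float = 2.0

    def __post_init__(self) -> None:
        self.zweights = np.asarray(self.zweights, dtype=np.float64)
        if self.cluster_size != len(self.member_components):
            raise ValueError("cluster_size must equal the number of members")

    @property
    def name(self) -> str:
        return f"MeC-{self.mec_id}"

    @property
    def significant_genes(self) -> np.ndarray:
        """Genes with averaged z-weight >= 2 (positive side)."""
        return self.gene_ids[self.zweights >= self.SIGNIFICANT_Z]

    def top_genes(self, n: int = 20) -> np.ndarray:
        order = np.argsort(-self.zweights, kind="stable")
        return self.gene_ids[order[:n]]


@dataclass
class MeCScoreMatrix:
    """Cells x MeCs projection scores; ``scores`` is the per-MeC z-scaled
    version of ``raw_scores``."""

    scores: np.ndarray
    raw_scores: np.ndarray
    cell_ids: np.ndarray
    mec_ids: list[str]
    genes_used_per_mec: dict = field(default_factory=dict)
    cluster_labels: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


@dataclass
class ClusterEnrichment:
    cluster_id: str
    enriched_mecs: list[tuple[str, float]]  # (mec_id, mean score), desc
    top_mec: Optional[str]
    state_label: str


@dataclass
class DifferentialRecord:
    cluster_id: str
    mec_id: str
    label: str
    effect: float
    p_value: float
    p_adjusted: float
    n1: int
    n2: int
    test: str
    favored_mean: float = float("nan")


@dataclass
class ResolutionScan:
    grid: list[float]
    n_clusters: list[int]
    silhouette: list[float]
    chosen_resolution: float
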