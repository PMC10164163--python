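"""Reading expression matrices, quality control and depth normalization.

Supported inputs are Matrix Market triplets with barcode/feature companions
(10x convention: genes x cells) and dense TSV/CSV tables in either
orientation. Cells are filtered on library size, detected-gene count and
mitochondrial read fraction; counts are depth-normalized and log1p
transformed.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import LogExpressionMatrix, RawCountMatrix

MITO_REGEX_DEFAULT = r"^MT-"

# QC defaults: minimum library size, minimum detected genes, maximum
# mitochondrial read fraction. Thresholds are inclusive.
MIN_LIB_DEFAULT = 1000
MIN_GENES_DEFAULT = 500
MAX_MITO_FRAC_DEFAULT = 0.05
TARGET_DEPTH_DEFAULT = 10000


class MatrixParseError(ValueError):
    """Raised when an input matrix file cannot be parsed."""


def _collapse_duplicate_genes(
    values: np.ndarray, gene_ids: np.ndarray, units: str
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicated gene symbols: sum for counts, max otherwise."""
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    df = pd.DataFrame(values.T, index=pd.Index(gene_ids, name="gene"))
    agg = "sum" if units == "counts" else "max"
    collapsed = df.groupby(level="gene", sort=False).agg(agg)
    return collapsed.to_numpy().T, collapsed.index.to_numpy(dtype=object)


def _find_companion(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in (".tsv", ".txt", ".tsv.gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise MatrixParseError(
        f"no companion file among {stems} found next to matrix in {directory}"
    )


def read_matrix(
    path: str | Path,
    format: str = "dense_table",
    dataset_id: str = "dataset",
    units: str = "counts",
    orientation: str = "genes_by_cells",
) -> RawCountMatrix:
    """Read one dataset into a :class:`RawCountMatrix`.

    Parameters
    ----------
    path
        For ``mtx_triplet``: the ``.mtx`` file or its directory, with
        ``barcodes.tsv`` and ``features.tsv``/``genes.tsv`` companions.
        For ``dense_table``: a TSV/CSV with gene and cell labels.
    orientation
        ``genes_by_cells`` (10x/MTX convention, the default) or
        ``cells_by_genes``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_triplet":
        mtx_path = path if path.is_file() else None
        directory = path.parent if path.is_file() else path
        if mtx_path is None:
            candidates = sorted(directory.glob("*.mtx"))
            if not candidates:
                raise MatrixParseError(f"no .mtx file in {directory}")
            mtx_path = candidates[0]
        try:
            mat = spio.mmread(mtx_path)
        except Exception as exc:  # scipy raises bare ValueError on bad lines
            raise MatrixParseError(f"failed to parse {mtx_path}: {exc}") from exc
        mat = sparse.coo_matrix(mat).toarray().astype(np.float64)
        barcodes = pd.read_csv(
            _find_companion(directory, ("barcodes",)), header=None, sep="\t"
        )[0].to_numpy(dtype=object)
        feat_path = _find_companion(directory, ("features", "genes"))
        features = pd.read_csv(feat_path, header=None, sep="\t")
        gene_col = 1 if features.shape[1] > 1 else 0
        genes = features[gene_col].to_numpy(dtype=object)
        if orientation == "genes_by_cells":
            values, cells = mat.T, barcodes
        else:
            values, cells = mat, barcodes
        if values.shape != (len(cells), len(genes)):
            raise MatrixParseError(
                f"{mtx_path}: matrix shape {mat.shape} inconsistent with "
                f"{len(genes)} features x {len(barcodes)} barcodes"
            )
    elif format == "dense_table":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise MatrixParseError(f"failed to parse {path}: {exc}") from exc
        if orientation == "genes_by_cells":
            df = df.T
        values = df.to_numpy(dtype=np.float64)
        cells = df.index.to_numpy(dtype=object)
        genes = df.columns.to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    if values.shape[0] == 0 or values.shape[1] == 0:
        raise MatrixParseError(f"{path}: empty matrix ({values.shape})")
    values, genes = _collapse_duplicate_genes(values, np.asarray(genes), units)
    return RawCountMatrix(
        values=values,
        cell_ids=cells,
        gene_ids=genes,
        dataset_id=dataset_id,
        units=units,
    )


def qc_filter(
    m: RawCountMatrix,
    min_lib: float = MIN_LIB_DEFAULT,
    min_genes: int = MIN_GENES_DEFAULT,
    max_mito_frac: float = MAX_MITO_FRAC_DEFAULT,
    mito_regex: str = MITO_REGEX_DEFAULT,
) -> RawCountMatrix:
    """Remove cells failing any QC threshold (thresholds inclusive).

    Library-size and mitochondrial filters apply to count data; for
    normalized units only the detected-gene filter is applied, with a
    warning. The mitochondrial filter is skipped when no gene matches
    ``mito_regex``.
    """
    counts_like = m.units == "counts"
    if not counts_like:
        warnings.warn(
            f"{m.dataset_id}: QC on {m.units} units applies only the "
            "detected-gene filter",
            UserWarning,
            stacklevel=2,
        )
    lib = m.values.sum(axis=1)
    n_genes_per_cell = (m.values > 0).sum(axis=1)
    keep = n_genes_per_cell >= min_genes
    removed = {"min_genes": int((~keep).sum())}
    if counts_like:
        pass_lib = lib >= min_lib
        removed["min_lib"] = int((keep & ~pass_lib).sum())
        keep &= pass_lib
        mito_mask = np.array(
            [bool(re.match(mito_regex, g, flags=re.IGNORECASE)) for g in m.gene_ids]
        )
        if mito_mask.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                mito_frac = np.where(
                    lib > 0, m.values[:, mito_mask].sum(axis=1) / np.maximum(lib, 1e-12), 0.0
                )
            pass_mito = mito_frac <= max_mito_frac
            removed["max_mito_frac"] = int((keep & ~pass_mito).sum())
            keep &= pass_mito
        else:
            removed["max_mito_frac"] = 0
    if not keep.any():
        raise ValueError(
            f"{m.dataset_id}: all {m.n_cells} cells removed by QC "
            f"(per-filter removals: {removed})"
        )
    out = RawCountMatrix(
        values=m.values[keep],
        cell_ids=m.cell_ids[keep],
        gene_ids=m.gene_ids,
        dataset_id=m.dataset_id,
        units=m.units,
    )
    out.qc_report = {  # type: ignore[attr-defined]
        "n_cells_in": int(m.n_cells),
        "n_cells_kept": int(keep.sum()),
        "filters_applied": {
            "min_lib": min_lib if counts_like else None,
            "min_genes": min_genes,
            "max_mito_frac": max_mito_frac if counts_like else None,
        },
        "removed": removed,
    }
    return out


def normalize_log(
    m: RawCountMatrix, target_depth: float = TARGET_DEPTH_DEFAULT
) -> LogExpressionMatrix:
    """Depth-normalize counts to ``target_depth`` per cell and log1p.

    TPM/FPKM input is log1p'ed without rescaling; log-normalized input
    passes through unchanged.
    """
    if m.values.size and m.values.min() < 0:
        raise ValueError("negative expression values")
    if m.units == "counts":
        depth = m.values.sum(axis=1, keepdims=True)
        scale = np.divide(
            target_depth, depth, out=np.zeros_like(depth), where=depth > 0
        )
        values = np.log1p(m.values * scale)
    elif m.units == "tpm_fpkm":
        values = np.log1p(m.values)
    else:  # lognorm
        values = m.values.copy()
    return LogExpressionMatrix(
        values=values,
        cell_ids=m.cell_ids,
        gene_ids=m.gene_ids,
        dataset_id=m.dataset_id,
        qc_report=getattr(m, "qc_report", {}),
    )


def harmonize_genes(
    datasets: list[LogExpressionMatrix], min_fraction: float = 1.0
) -> tuple[list[LogExpressionMatrix], np.ndarray]:
    """Restrict all datasets to a shared, identically ordered gene universe.

    The universe is the set of genes present in at least ``min_fraction`` of
    the datasets (1.0 = strict intersection). Genes missing from a dataset
    are zero-filled (only possible when ``min_fraction`` < 1).
    """
    if len(datasets) < 2:
        raise ValueError("harmonize_genes needs at least 2 datasets")
    counts: dict[str, int] = {}
    for d in datasets:
        for g in d.gene_ids:
            counts[g] = counts.get(g, 0) + 1
    need = min_fraction * len(datasets)
    universe = np.asarray(sorted(g for g, c in counts.items() if c >= need), dtype=object)
    if universe.size == 0:
        raise ValueError("empty shared gene universe across datasets")
    out = []
    for d in datasets:
        idx = {g: j for j, g in enumerate(d.gene_ids)}
        values = np.zeros((d.n_cells, universe.size))
        for j, g in enumerate(universe):
            if g in idx:
                values[:, j] = d.values[:, idx[g]]
        out.append(
            LogExpressionMatrix(
                values=values,
                cell_ids=d.cell_ids,
                gene_ids=universe.copy(),
                dataset_id=d.dataset_id,
                qc_report=d.qc_report,
            )
        )
    return out, universe


def process_dataset(
    m: RawCountMatrix,
    apply_qc: bool = True,
    min_lib: float = MIN_LIB_DEFAULT,
    min_genes: int = MIN_GENES_DEFAULT,
    max_mito_frac: float = MAX_MITO_FRAC_DEFAULT,
    target_depth: float = TARGET_DEPTH_DEFAULT,
) -> LogExpressionMatrix:
    """QC + normalization convenience wrapper used by the CLI and benchmark."""
    if apply_qc and m.units != "lognorm":
        m = qc_filter(m, min_lib=min_lib, min_genes=min_genes, max_mito_frac=max_mito_frac)
    return normalize_log(m, target_depth=target_depth)
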