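"""Per-dataset matrix decomposition into gene z-weight components.

Each dataset's log expression matrix (cells x genes) is decomposed with
FastICA (logcosh contrast, whitening on) into k independent components in
gene space plus per-cell loadings. Two normalizations make components
comparable across datasets: a z-score transform of the gene loadings of
each component, and a sign flip so the weight distribution has
non-negative skewness (ICA signs are arbitrary; positive skew puts the
representative genes on the positive tail).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.decomposition import NMF, FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import Component, DecompositionResult, LogExpressionMatrix

DEFAULT_K = 100
# Tight convergence so repeated runs on identical data land on the same
# components regardless of initialization.
ICA_TOL = 1e-7
ICA_MAX_ITER = 1000


def z_normalize(raw_loadings: np.ndarray) -> np.ndarray:
    """Full z-score of a gene loading vector (population SD)."""
    x = np.asarray(raw_loadings, dtype=np.float64)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-normalize a zero-variance loading vector")
    return (x - x.mean()) / sd


def align_skewness(c: Component) -> Component:
    """Flip a component's sign if its z-weight distribution is left-skewed.

    The decision uses the sign of the sample skewness (third standardized
    moment); the skewness-test statistic is recorded for reporting when the
    vector is long enough for the test to be defined.
    """
    z = c.zweights
    skew = stats.skew(z)
    flipped = bool(skew < 0)
    if flipped:
        z = -z
    if z.size >= 8:
        with np.errstate(all="ignore"):
            stat = float(stats.skewtest(z).statistic)
    else:
        stat = float(stats.skew(z))
    return Component(
        zweights=z,
        dataset_id=c.dataset_id,
        component_index=c.component_index,
        skew_stat=stat,
        flipped=flipped ^ c.flipped,
    )


def _postprocess_loadings(
    raw: np.ndarray,
    kept: np.ndarray,
    n_genes: int,
    dataset_id: str,
) -> list[Component]:
    """z-normalize each raw gene-loading row on the kept-gene support,
    re-insert dropped genes as exact zeros, and align skewness."""
    comps = []
    for i, row in enumerate(raw):
        z = np.zeros(n_genes)
        z[kept] = z_normalize(row)
        comps.append(
            align_skewness(
                Component(zweights=z, dataset_id=dataset_id, component_index=i)
            )
        )
    return comps


def decompose_dataset(
    m: LogExpressionMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    method: str = "ica",
    max_iter: int = ICA_MAX_ITER,
    tol: float = ICA_TOL,
) -> DecompositionResult:
    """Decompose one dataset into ``k`` sign-aligned gene z-weight components.

    ``k`` is clipped to ``min(n_cells, n_genes) - 1`` with a warning when the
    matrix is too small. Zero-variance genes are dropped before the
    decomposition and re-inserted as zero z-weights. A non-convergent ICA run
    is retried once with ``seed + 1`` and accepted (flagged) if it still does
    not converge.

    ``method='nmf'`` substitutes non-negative matrix factorization, whose
    components then pass through the same z-normalization/alignment path;
    this exists for benchmarking against ICA.
    """
    X = m.values
    variances = X.var(axis=0)
    kept = variances > 0
    if not kept.any():
        raise ValueError(f"{m.dataset_id}: matrix has no gene with nonzero variance")
    Xk = X[:, kept]
    max_k = min(Xk.shape) - 1
    if k > max_k:
        warnings.warn(
            f"{m.dataset_id}: k={k} exceeds min(n_cells, n_genes)-1={max_k}; "
            f"reduced to {max_k}",
            UserWarning,
            stacklevel=2,
        )
        k = max_k
    if k < 1:
        raise ValueError(f"{m.dataset_id}: matrix too small to decompose")

    if method == "ica":
        loadings, raw_components, converged, used_seed = _fit_ica(
            Xk, k, seed, max_iter, tol
        )
    elif method == "nmf":
        model = NMF(
            n_components=k,
            init="nndsvda",
            random_state=seed,
            max_iter=max(200, max_iter // 2),
            tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            loadings = model.fit_transform(Xk)
        raw_components = model.components_
        converged = model.n_iter_ < model.max_iter
        used_seed = seed
    else:
        raise ValueError(f"unknown method {method!r}")

    components = _postprocess_loadings(raw_components, kept, m.n_genes, m.dataset_id)
    return DecompositionResult(
        components=components,
        cell_loadings=loadings,
        gene_ids=m.gene_ids.copy(),
        cell_ids=m.cell_ids.copy(),
        dataset_id=m.dataset_id,
        k=k,
        seed=used_seed,
        converged=converged,
    )


def _fit_ica(
    X: np.ndarray, k: int, seed: int, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    for attempt_seed in (seed, seed + 1):
        ica = FastICA(
            n_components=k,
            fun="logcosh",
            whiten="unit-variance",
            random_state=attempt_seed,
            max_iter=max_iter,
            tol=tol,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            loadings = ica.fit_transform(X)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        if converged:
            return loadings, ica.components_, True, attempt_seed
    return loadings, ica.components_, False, attempt_seed
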