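"""Synthetic multi-cohort scRNA-seq counts with planted expression programs.

The generator emulates the study conditions used to benchmark component
discovery: a set of cohorts, each expressing a random subset of shared
cell-identity gene-expression programs (GEPs) plus one activity program
that switches on across cell types, with counts drawn from a hierarchical
gamma-Poisson model (lognormal baseline gene means, multiplicative program
factors, lognormal library sizes).

Defaults define the standard fixture: 14 programs (13 identity + 1
activity) of 50 genes each with factors uniform in [2, 6], 1000 genes,
500 cells per cohort, baseline means lognormal(mu=0.5, sigma=1), depths
lognormal(mu=9, sigma=0.3), per-cohort identity subsets of size uniform in
[5, 13] and activity-program presence with probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import decomposition, discovery, io
from .containers import LogExpressionMatrix, MeC, MeCScoreMatrix, RawCountMatrix

N_IDENTITY_DEFAULT = 13
N_ACTIVITY_DEFAULT = 1
GENES_PER_PROGRAM_DEFAULT = 50
N_GENES_DEFAULT = 1000
CELLS_PER_DATASET_DEFAULT = 500
N_DATASETS_DEFAULT = 20
FACTOR_RANGE_DEFAULT = (2.0, 6.0)
BASELINE_LOGNORMAL = (0.5, 1.0)  # (mu, sigma) of per-gene baseline means
DEPTH_LOGNORMAL = (9.0, 0.3)  # (mu, sigma) of per-cell library sizes
IDENTITY_SUBSET_RANGE = (5, 13)  # cohort carries this many identity programs
ACTIVITY_COHORT_PROB = 0.5  # cohort carries the activity program
ACTIVITY_CELL_PROB = 0.5  # carrier-cohort cell switches the program on
ACTIVITY_STRENGTH_RANGE = (0.5, 1.0)  # per-cell interpolation toward full factor
BCV = 0.2  # biological coefficient of variation of the gamma noise


@dataclass
class GEPTruth:
    """Ground truth of the simulation.

    ``gep_matrix`` holds one multiplicative scaling-factor row per program
    (1.0 outside the program's member genes). Per-cohort subsets and
    per-cell assignments are filled in by :func:`simulate_cohorts`.
    """

    gep_matrix: np.ndarray  # programs x genes, positive factors
    gene_ids: np.ndarray
    program_kind: list[str]  # "identity" | "activity" per program
    base_means: np.ndarray  # per-gene baseline relative means
    cohort_programs: dict[str, list[int]] = field(default_factory=dict)
    cell_truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.gep_matrix <= 0).any():
            raise ValueError("program scaling factors must be positive")

    @property
    def n_programs(self) -> int:
        return self.gep_matrix.shape[0]

    @property
    def identity_programs(self) -> list[int]:
        return [i for i, k in enumerate(self.program_kind) if k == "identity"]

    @property
    def activity_programs(self) -> list[int]:
        return [i for i, k in enumerate(self.program_kind) if k == "activity"]


def make_truth(
    n_genes: int = N_GENES_DEFAULT,
    n_identity: int = N_IDENTITY_DEFAULT,
    n_activity: int = N_ACTIVITY_DEFAULT,
    genes_per_program: int = GENES_PER_PROGRAM_DEFAULT,
    factor_range: tuple[float, float] = FACTOR_RANGE_DEFAULT,
    seed: int = 0,
) -> GEPTruth:
    """Build the program ground truth: disjoint gene blocks with random
    multiplicative factors, plus lognormal baseline gene means."""
    n_programs = n_identity + n_activity
    if n_programs * genes_per_program > n_genes:
        raise ValueError("programs do not fit in the gene universe")
    rng = np.random.default_rng(seed)
    gep = np.ones((n_programs, n_genes))
    for p in range(n_programs):
        lo = p * genes_per_program
        members = np.arange(lo, lo + genes_per_program)
        gep[p, members] = rng.uniform(*factor_range, size=genes_per_program)
    gene_ids = np.asarray([f"g{j:04d}" for j in range(n_genes)], dtype=object)
    base = rng.lognormal(*BASELINE_LOGNORMAL, size=n_genes)
    kinds = ["identity"] * n_identity + ["activity"] * n_activity
    return GEPTruth(
        gep_matrix=gep, gene_ids=gene_ids, program_kind=kinds, base_means=base
    )


def simulate_cohorts(
    truth: GEPTruth,
    n_datasets: int = N_DATASETS_DEFAULT,
    cells_per_dataset: int = CELLS_PER_DATASET_DEFAULT,
    seed: int = 0,
    bcv: float = BCV,
) -> list[RawCountMatrix]:
    """Draw ``n_datasets`` cohort count matrices carrying subsets of the
    truth programs; per-cohort subsets and per-cell assignments are recorded
    on ``truth``. Fully deterministic given (truth, seed)."""
    if cells_per_dataset < 50:
        raise ValueError("cells_per_dataset must be >= 50")
    if (truth.gep_matrix <= 0).any():
        raise ValueError("program scaling factors must be positive")
    rng = np.random.default_rng(seed)
    identity = truth.identity_programs
    activity = truth.activity_programs
    # clamp the subset-size range to the number of identity programs
    lo = min(IDENTITY_SUBSET_RANGE[0], len(truth.identity_programs))
    hi = min(IDENTITY_SUBSET_RANGE[1], len(truth.identity_programs))
    cohorts = []
    for d in range(n_datasets):
        dataset_id = f"cohort{d:02d}"
        n_id = int(rng.integers(lo, hi + 1))
        chosen = sorted(rng.choice(identity, size=n_id, replace=False).tolist())
        has_activity = bool(activity) and rng.random() < ACTIVITY_COHORT_PROB
        programs = chosen + (activity if has_activity else [])
        truth.cohort_programs[dataset_id] = programs

        ident_of_cell = rng.choice(chosen, size=cells_per_dataset)
        act_on = (
            rng.random(cells_per_dataset) < ACTIVITY_CELL_PROB
            if has_activity
            else np.zeros(cells_per_dataset, dtype=bool)
        )
        strength = rng.uniform(*ACTIVITY_STRENGTH_RANGE, size=cells_per_dataset)

        means = np.tile(truth.base_means, (cells_per_dataset, 1))
        for p in set(ident_of_cell):
            means[ident_of_cell == p] *= truth.gep_matrix[p]
        if has_activity:
            a = activity[0]
            # graded activity: interpolate factors toward 1 by cell strength
            fac = 1.0 + strength[act_on, None] * (truth.gep_matrix[a][None, :] - 1.0)
            means[act_on] *= fac
        if bcv > 0:
            shape = 1.0 / bcv**2
            means *= rng.gamma(shape, 1.0 / shape, size=means.shape)
        probs = means / means.sum(axis=1, keepdims=True)
        depth = rng.lognormal(*DEPTH_LOGNORMAL, size=cells_per_dataset)
        counts = rng.poisson(depth[:, None] * probs).astype(np.float64)

        cell_ids = np.asarray(
            [f"{dataset_id}_c{i:04d}" for i in range(cells_per_dataset)], dtype=object
        )
        truth.cell_truth[dataset_id] = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "identity_program": ident_of_cell,
                "activity_on": act_on,
                "activity_strength": np.where(act_on, strength, 0.0),
            }
        )
        cohorts.append(
            RawCountMatrix(
                values=counts,
                cell_ids=cell_ids,
                gene_ids=truth.gene_ids.copy(),
                dataset_id=dataset_id,
                units="counts",
            )
        )
    return cohorts


def prepare_cohorts(
    cohorts: Sequence[RawCountMatrix], apply_qc: bool = False
) -> list[LogExpressionMatrix]:
    """Normalize/log the cohorts onto the shared simulated gene axis."""
    logs = [io.process_dataset(c, apply_qc=apply_qc) for c in cohorts]
    harmonized, _ = io.harmonize_genes(logs)
    return harmonized


@dataclass
class RecoveryReport:
    """How well predicted programs match the planted truth."""

    method: str
    n_cohorts: int
    match_matrix: np.ndarray  # predicted x true Pearson r
    best_match: list[tuple[Optional[int], float]]  # per true program
    independence: float  # mean |pairwise r| among predicted

    def recovered_fraction(self, threshold: float = 0.7) -> float:
        if not self.best_match:
            return 0.0
        return float(
            np.mean([(p is not None and r >= threshold) for p, r in self.best_match])
        )


def truth_vectors(truth: GEPTruth) -> np.ndarray:
    """Programs x genes vectors comparable to MeC z-weights: log factors,
    z-scored per program (Pearson correlation is affine-invariant, so the
    exact transform only matters for numerical conditioning)."""
    logf = np.log(truth.gep_matrix)
    mean = logf.mean(axis=1, keepdims=True)
    sd = logf.std(axis=1, keepdims=True)
    return (logf - mean) / np.where(sd > 0, sd, 1.0)


def evaluate_recovery(
    predicted: Sequence[MeC],
    truth: GEPTruth,
    method: str = "ica",
    n_cohorts: int = 0,
    greedy: bool = False,
) -> RecoveryReport:
    """Match predicted MeCs to true programs by Pearson correlation with a
    one-to-one optimal (Hungarian) assignment; also report predicted-set
    mutual independence (mean absolute off-diagonal correlation)."""
    tv = truth_vectors(truth)
    n_true = tv.shape[0]
    if not len(predicted):
        return RecoveryReport(
            method=method, n_cohorts=n_cohorts,
            match_matrix=np.zeros((0, n_true)),
            best_match=[(None, float("-inf"))] * n_true,
            independence=float("nan"),
        )
    P = np.vstack([m.zweights for m in predicted])
    corr = np.corrcoef(np.vstack([P, tv]))[: len(predicted), len(predicted):]
    corr = np.nan_to_num(corr, nan=0.0)
    if greedy:
        pairs = _greedy_match(corr)
    else:
        # Hungarian on padded square cost so unmatched programs are allowed
        row, col = linear_sum_assignment(-corr)
        pairs = {int(c): int(r) for r, c in zip(row, col)}
    best = [
        (pairs.get(t), float(corr[pairs[t], t]) if t in pairs else float("-inf"))
        for t in range(n_true)
    ]
    if len(predicted) > 1:
        pp = np.corrcoef(P)
        iu = np.triu_indices(len(predicted), k=1)
        independence = float(np.abs(pp[iu]).mean())
    else:
        independence = 0.0
    return RecoveryReport(
        method=method, n_cohorts=n_cohorts, match_matrix=corr,
        best_match=best, independence=independence,
    )


def _greedy_match(corr: np.ndarray) -> dict[int, int]:
    """Repeatedly take the best remaining (predicted, true) pair."""
    pairs: dict[int, int] = {}
    c = corr.copy()
    n_pred, n_true = c.shape
    for _ in range(min(n_pred, n_true)):
        r, t = np.unravel_index(np.argmax(c), c.shape)
        pairs[int(t)] = int(r)
        c[r, :] = -np.inf
        c[:, t] = -np.inf
    return pairs


def run_recovery(
    cohorts: Sequence[RawCountMatrix] | Sequence[LogExpressionMatrix],
    method: str = "ica",
    k: int = 20,
    seed: int = 0,
    min_corr: float = discovery.MIN_CORR_DEFAULT,
    min_cluster_size: int = discovery.MIN_CLUSTER_SIZE_DEFAULT,
    resolution: float | str = "auto",
) -> list[MeC]:
    """Per-cohort decomposition (ICA or NMF) + the MeC discovery pipeline,
    returning predicted programs as MeCs."""
    if len(cohorts) < 2:
        raise ValueError("program recovery needs >=2 cohorts")
    if isinstance(cohorts[0], RawCountMatrix):
        logs = prepare_cohorts(cohorts)  # type: ignore[arg-type]
    else:
        logs = list(cohorts)  # type: ignore[assignment]
    run = discovery.discover_mecs(
        logs, k=k, seed=seed, method=method, min_corr=min_corr,
        min_cluster_size=min_cluster_size, resolution=resolution,
    )
    return run.mecs


def cohort_count_sweep(
    truth: GEPTruth,
    cohorts: Sequence[RawCountMatrix],
    counts: Sequence[int] = (5, 10, 20),
    method: str = "ica",
    k: int = 20,
    seed: int = 0,
    resolution: float | str = "auto",
    min_cluster_size: int = discovery.MIN_CLUSTER_SIZE_DEFAULT,
) -> dict[int, RecoveryReport]:
    """Recovery at nested cohort subsets (first 5, first 10, ...) sharing
    one set of per-cohort decompositions."""
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    if max(counts) > len(cohorts):
        raise ValueError("not enough simulated cohorts for the requested sweep")
    logs = prepare_cohorts(cohorts)
    results = [
        decomposition.decompose_dataset(d, k=k, seed=seed, method=method)
        for d in logs
    ]
    reports = {}
    for c in sorted(counts):
        run = discovery.discover_from_decompositions(
            results[:c], resolution=resolution,
            min_cluster_size=min_cluster_size, seed=seed,
        )
        reports[c] = evaluate_recovery(run.mecs, truth, method=method, n_cohorts=c)
    return reports


def cross_cluster_entropy(
    scores: MeCScoreMatrix, labels: Sequence[str]
) -> pd.Series:
    """Information content of each signature relative to cell clusters.

    Per signature, the mean positive-part score within each cluster is
    normalized to a distribution over clusters; the entropy (natural log)
    of that distribution is returned. 0 = perfectly cluster-specific,
    log(n_clusters) = uninformative. An all-zero signature reports the
    maximal entropy.
    """
    labels = np.asarray(labels, dtype=object)
    clusters = sorted(set(labels), key=str)
    if len(clusters) < 2:
        raise ValueError("cross-cluster entropy needs >=2 clusters")
    pos = np.clip(scores.scores, 0.0, None)
    out = {}
    for j, mec in enumerate(scores.mec_ids):
        m = np.asarray([pos[labels == c, j].mean() for c in clusters])
        total = m.sum()
        if total == 0:
            out[mec] = float(np.log(len(clusters)))  # uninformative signature
            continue
        p = m / total
        nz = p[p > 0]
        out[mec] = float(-(nz * np.log(nz)).sum())
    return pd.Series(out, name="cross_cluster_entropy")
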