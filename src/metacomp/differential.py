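"""Differential MeC signature testing between two conditions.

Within each annotated cell cluster, every MeC enriched in that cluster
(mean scaled score >= 2) is compared between the two conditions with a
two-sided Welch t-test (or Wilcoxon rank-sum). The effect size is the
difference of condition means; Benjamini-Hochberg adjusted p-values are
reported alongside the raw ones.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DifferentialRecord, MeCScoreMatrix
from .annotator import ENRICHMENT_CUTOFF, enrich_clusters

MIN_CELLS_DEFAULT = 10


def _two_sample_test(x1: np.ndarray, x2: np.ndarray, test: str) -> float:
    if np.ptp(np.concatenate([x1, x2])) == 0:
        return 1.0  # constant scores carry no evidence
    if test == "t":
        res = stats.ttest_ind(x2, x1, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(x2, x1, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def differential_mec(
    scores: MeCScoreMatrix,
    labels: Sequence[str],
    conditions: Sequence[str],
    test: str = "t",
    min_cells: int = MIN_CELLS_DEFAULT,
    cutoff: float = ENRICHMENT_CUTOFF,
    condition_order: Optional[tuple[str, str]] = None,
) -> list[DifferentialRecord]:
    """Per-(cluster, enriched MeC) two-condition comparison of MeC scores.

    ``effect`` is mean(condition2) - mean(condition1), with the condition
    order taken from ``condition_order`` or sorted unique values. Clusters
    missing a condition or with fewer than ``min_cells`` cells in either are
    skipped. ``favored_mean`` is the mean score in the condition favored by
    the effect sign (the quantity the significance-effect scatter sizes its
    dots by).
    """
    labels = np.asarray(labels, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    if labels.shape[0] != scores.n_cells or conditions.shape[0] != scores.n_cells:
        raise ValueError("labels and conditions must cover all cells")
    uniq = sorted(set(conditions), key=str)
    if condition_order is None:
        if len(uniq) != 2:
            raise ValueError(f"need exactly 2 conditions, got {uniq}")
        cond1, cond2 = uniq
    else:
        cond1, cond2 = condition_order
    enrichments = enrich_clusters(scores, labels, cutoff=cutoff)
    mec_index = {m: j for j, m in enumerate(scores.mec_ids)}
    records: list[DifferentialRecord] = []
    for enr in enrichments:
        in_cluster = labels == enr.cluster_id
        m1 = in_cluster & (conditions == cond1)
        m2 = in_cluster & (conditions == cond2)
        if m1.sum() < min_cells or m2.sum() < min_cells:
            continue  # condition absent or underpowered in this cluster
        for mec_id, _ in enr.enriched_mecs:
            col = mec_index[mec_id]
            x1 = scores.scores[m1, col]
            x2 = scores.scores[m2, col]
            effect = float(x2.mean() - x1.mean())
            p = _two_sample_test(x1, x2, test)
            label = (
                enr.state_label
                if mec_id == enr.top_mec
                else f"{mec_id}@{enr.state_label}"
            )
            records.append(
                DifferentialRecord(
                    cluster_id=enr.cluster_id,
                    mec_id=mec_id,
                    label=label,
                    effect=effect,
                    p_value=p,
                    p_adjusted=np.nan,
                    n1=int(m1.sum()),
                    n2=int(m2.sum()),
                    test=test,
                    favored_mean=float(x2.mean() if effect >= 0 else x1.mean()),
                )
            )
    if records:
        adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, adj):
            r.p_adjusted = float(q)
    return records


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Tabular view of differential records, sortable for the
    significance-effect scatter."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster_id,
                "mec": r.mec_id,
                "label": r.label,
                "effect": r.effect,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "neg_log10_p": -np.log10(max(r.p_value, 1e-300)),
                "n1": r.n1,
                "n2": r.n2,
                "test": r.test,
                "favored_mean": r.favored_mean,
            }
            for r in records
        ]
    )
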