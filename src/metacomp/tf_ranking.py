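"""Transcription-factor prioritization per meta-component.

Combines two evidence sources per (MeC, TF): the TF's expression
representation in the MeC (its gene z-weight) and a precomputed
regulatory-potential significance score (-log10 p, e.g. from a ChIP-seq
based tool), supplied as a TF x MeC table. TFs are classified into:

* ``both_significant`` ("TF_MeCLisa_top_1"): z-weight >= 2 and -log10 p >= 2;
* ``both_top40`` ("TF_MeCLisa_top"): both_significant and aggregated rank
  (mean of the z-weight rank among all genes and the regulatory-score rank
  among scored TFs) <= 40;
* ``mec_only_top10`` ("TF_MeC_top"): among the 10 highest-z-weight TFs but
  not both_significant;
* ``lisa_only_top10`` ("TF_Lisa_top"): among the 10 most regulatory-
  significant TFs but not both_significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import MeC

Z_CUTOFF = 2.0
NEGLOGP_CUTOFF = 2.0
TOP_AGGREGATED = 40
TOP_SINGLE = 10


@dataclass
class TFScoreTable:
    """TF x MeC regulatory significance (-log10 p) plus looked-up z-weights."""

    tf_names: list[str]
    lisa_neglogp: pd.DataFrame  # TF x MeC
    mec_zweight: pd.DataFrame  # TF x MeC

    def __post_init__(self) -> None:
        if (self.lisa_neglogp.to_numpy() < 0).any():
            raise ValueError("-log10 p regulatory scores must be >= 0")


def build_tf_table(
    lisa: pd.DataFrame, mecs: Sequence[MeC], tf_catalog: Sequence[str]
) -> TFScoreTable:
    """Align a TF x MeC -log10 p table with MeC z-weights for catalog TFs.

    TFs absent from the MeC gene universe get z-weight 0 (with a note);
    rows of ``lisa`` not in the catalog are rejected.
    """
    unknown = set(lisa.index) - set(tf_catalog)
    if unknown:
        raise ValueError(f"TFs absent from the catalog: {sorted(unknown)[:5]} ...")
    mec_names = [m.name for m in mecs]
    missing_cols = set(map(str, lisa.columns)) - set(mec_names)
    if missing_cols:
        raise ValueError(f"score table columns not among MeCs: {sorted(missing_cols)}")
    tf_names = [str(t) for t in lisa.index]
    z = pd.DataFrame(0.0, index=lisa.index, columns=lisa.columns)
    absent = []
    for m in mecs:
        if m.name not in lisa.columns:
            continue
        gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
        for tf in tf_names:
            if tf in gene_pos:
                z.loc[tf, m.name] = m.zweights[gene_pos[tf]]
            else:
                absent.append(tf)
    if absent:
        warnings.warn(
            f"{len(set(absent))} catalog TFs absent from the MeC gene universe; "
            "z-weight treated as 0", UserWarning, stacklevel=2,
        )
    return TFScoreTable(tf_names=tf_names, lisa_neglogp=lisa.astype(float),
                        mec_zweight=z)


def classify_tfs(table: TFScoreTable, mecs: Sequence[MeC]) -> pd.DataFrame:
    """Per-(MeC, TF) classification flags and aggregated rank.

    Returns a long DataFrame with columns mec, tf, zweight, neglogp,
    rank_mec_genes (z-weight rank among all genes), rank_mec_tfs,
    rank_lisa, aggregated_rank, and the four boolean flag columns.
    """
    mec_by_name = {m.name: m for m in mecs}
    rows = []
    for mec_name in table.lisa_neglogp.columns:
        mec = mec_by_name[str(mec_name)]
        z_tf = table.mec_zweight[mec_name].to_numpy()
        p_tf = table.lisa_neglogp[mec_name].to_numpy()
        # rank of each TF's z-weight against the full gene universe
        # (competition ranking: 1 = largest)
        all_z = np.sort(mec.zweights)[::-1]
        rank_genes = np.searchsorted(-all_z, -z_tf, side="left") + 1
        rank_mec_tfs = rankdata(-z_tf, method="min")
        rank_lisa = rankdata(-p_tf, method="min")
        aggregated = (rank_genes + rank_lisa) / 2.0
        both_sig = (z_tf >= Z_CUTOFF) & (p_tf >= NEGLOGP_CUTOFF)
        both_top40 = both_sig & (aggregated <= TOP_AGGREGATED)
        mec_only = (rank_mec_tfs <= TOP_SINGLE) & ~both_sig
        lisa_only = (rank_lisa <= TOP_SINGLE) & ~both_sig
        for i, tf in enumerate(table.tf_names):
            rows.append(
                {
                    "mec": str(mec_name),
                    "tf": tf,
                    "zweight": float(z_tf[i]),
                    "neglogp": float(p_tf[i]),
                    "rank_mec_genes": int(rank_genes[i]),
                    "rank_mec_tfs": int(rank_mec_tfs[i]),
                    "rank_lisa": int(rank_lisa[i]),
                    "aggregated_rank": float(aggregated[i]),
                    "TF_MeCLisa_top_1": bool(both_sig[i]),
                    "TF_MeCLisa_top": bool(both_top40[i]),
                    "TF_MeC_top": bool(mec_only[i]),
                    "TF_Lisa_top": bool(lisa_only[i]),
                }
            )
    return pd.DataFrame(rows)


def read_lisa_table(path: str | Path) -> pd.DataFrame:
    """TSV of TF x MeC -log10 p values (first column = TF names)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_tf_catalog(path: str | Path) -> list[str]:
    """One-column TF name list."""
    return (
        pd.read_csv(path, header=None, sep="\t")[0].astype(str).tolist()
    )
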