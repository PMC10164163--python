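"""Flat-file output/input for discovery results and score matrices."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MeC, MeCScoreMatrix


def mecs_to_frame(mecs: Sequence[MeC]) -> pd.DataFrame:
    """Genes x MeCs z-weight table."""
    if not len(mecs):
        raise ValueError("no MeCs to tabulate")
    return pd.DataFrame(
        {m.name: m.zweights for m in mecs},
        index=pd.Index(mecs[0].gene_ids, name="gene"),
    )


def write_mecs(mecs: Sequence[MeC], directory: str | Path) -> None:
    """Write the z-weight table, membership table and significant-gene lists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mecs_to_frame(mecs).to_csv(directory / "mec_weights.tsv", sep="\t")
    members = pd.DataFrame(
        [
            {"mec": m.name, "dataset_id": d, "component_index": i,
             "cluster_size": m.cluster_size}
            for m in mecs
            for d, i in m.member_components
        ]
    )
    members.to_csv(directory / "mec_members.tsv", sep="\t", index=False)
    sig = pd.DataFrame(
        [
            {"mec": m.name, "gene": g,
             "zweight": float(m.zweights[list(m.gene_ids).index(g)])}
            for m in mecs
            for g in m.significant_genes
        ]
    )
    sig.to_csv(directory / "mec_significant_genes.tsv", sep="\t", index=False)


def read_mecs(path: str | Path) -> list[MeC]:
    """Rebuild MeCs from a genes x MeCs z-weight TSV (membership unknown)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = df.index.to_numpy(dtype=object)
    mecs = []
    for col in df.columns:
        mec_id = int(str(col).split("-")[-1]) if "-" in str(col) else len(mecs)
        mecs.append(
            MeC(
                mec_id=mec_id,
                zweights=df[col].to_numpy(dtype=float),
                gene_ids=genes,
                member_components=[],
                cluster_size=0,
            )
        )
    return mecs


def scores_to_frame(scores: MeCScoreMatrix, scaled: bool = True) -> pd.DataFrame:
    values = scores.scores if scaled else scores.raw_scores
    return pd.DataFrame(
        values, index=pd.Index(scores.cell_ids, name="cell"), columns=scores.mec_ids
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
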