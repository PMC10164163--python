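"""Prioritize transcription-factor regulators of a meta-component.

Combines each TF's expression representation in the MeC (gene z-weight)
with a precomputed regulatory-potential significance (-log10 p, e.g. from
ChIP-seq based inference) and classifies TFs into jointly significant,
expression-only and binding-only groups.
"""

import numpy as np
import pandas as pd

from metacomp import build_tf_table, classify_tfs
from metacomp.containers import MeC

rng = np.random.default_rng(0)
tfs = [f"TF{j:02d}" for j in range(15)]
genes = tfs + [f"g{j:03d}" for j in range(185)]
z = rng.normal(0, 1, 200)
z[0], z[1], z[2] = 4.0, 3.0, 0.1  # TF00/TF01 highly expressed in the MeC
mec = MeC(mec_id=0, zweights=z, gene_ids=np.asarray(genes, dtype=object),
          member_components=[("d", i) for i in range(5)], cluster_size=5)

neglogp = rng.uniform(0, 1.5, 15)
neglogp[0], neglogp[2] = 6.0, 5.0  # TF00/TF02 strong binding evidence
lisa = pd.DataFrame({"MeC-0": neglogp}, index=tfs)

table = build_tf_table(lisa, [mec], tfs)
out = classify_tfs(table, [mec])
cols = ["tf", "zweight", "neglogp", "aggregated_rank",
        "TF_MeCLisa_top_1", "TF_MeC_top", "TF_Lisa_top"]
show = out[(out["zweight"] >= 2) | (out["neglogp"] >= 2)]
print(show[cols].to_string(index=False))
# TF00 is jointly significant (candidate autoregulator), TF01 is
# expression-only, TF02 binding-only - the three evidence classes.
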