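"""Differential MeC signature testing between two conditions.

Builds a scored cell population with one cluster, plants a +0.8 SD shift
in one enriched signature between 'pre' and 'post' conditions, and runs
the per-cluster two-sided Welch test over all enriched MeCs.
"""

import numpy as np

from metacomp import differential_mec, records_to_frame
from metacomp.containers import MeCScoreMatrix

rng = np.random.default_rng(0)
n = 300
values = np.column_stack([
    rng.normal(2.6, 1.0, n),  # enriched, unchanged
    rng.normal(2.4, 1.0, n),  # enriched, shifted post-treatment
    rng.normal(0.0, 1.0, n),  # not enriched -> never tested
])
conditions = np.array(["pre"] * 150 + ["post"] * 150, dtype=object)
values[conditions == "post", 1] += 0.8

scores = MeCScoreMatrix(
    scores=values, raw_scores=values,
    cell_ids=np.asarray([f"c{i}" for i in range(n)], dtype=object),
    mec_ids=["MeC-0", "MeC-1", "MeC-2"],
)
records = differential_mec(scores, ["T-cell"] * n, conditions,
                           condition_order=("pre", "post"))
print(records_to_frame(records)[
    ["label", "effect", "p_value", "p_adjusted", "n1", "n2"]
].to_string(index=False))
# The shifted MeC shows a ~0.8 effect (difference of condition means) at
# vanishing p; the unchanged one is flat. MeC-2 is absent: only signatures
# enriched in the cluster are tested.
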