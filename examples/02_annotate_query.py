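"""Annotate a new dataset with discovered meta-components.

Projects a held-out simulated cohort onto MeCs learned from the other
cohorts, over-clusters the cells at high resolution, and labels each
cluster with its most enriched MeC (mean scaled score >= 2).
"""

from collections import Counter

import metacomp as mc
from metacomp import io as mio

truth = mc.make_truth(seed=1)
cohorts = mc.simulate_cohorts(truth, n_datasets=9, cells_per_dataset=400, seed=1)

mecs = mc.run_recovery(cohorts[:8], method="ica", k=20, seed=1,
                       min_cluster_size=3)
query = mio.normalize_log(cohorts[8])
scored, enrichments = mc.annotate(query, mecs, resolution=8, seed=1)

states = Counter(
    next(e.state_label for e in enrichments if e.cluster_id == str(label))
    for label in scored.cluster_labels
)
print(f"MeCs used for projection: {len(mecs)}")
print(f"over-clusters at resolution 8: {len(enrichments)}")
print("cells per called state:")
for state, n in states.most_common():
    print(f"  {state:12s} {n}")
# Each state label is the MeC whose mean scaled score in that cluster passes
# the significance cutoff; cells of one planted cell type share a state.
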