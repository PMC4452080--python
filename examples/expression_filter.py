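"""Two-color expression filtering and clustering at desk scale.

Simulates a 5000-gene, 5-condition x 4-replicate two-color array set with
5% of genes differentially expressed, applies per-chip lowess
normalization, the per-condition replicate t-test, and the 2.5-fold
selection rule, then clusters the selected genes' condition profiles.
"""

import numpy as np

from dynsurf import SimulationConfig, hierarchical_cluster, normalize, select_genes
from dynsurf.simulate import gen_expression

config = SimulationConfig(seed=1, n_genes=5000, de_fraction=0.05)
matrix, truth = gen_expression(config)
normalized = normalize(matrix)
result = select_genes(normalized, fold_threshold=2.5, alpha=0.05, direction="both")

planted = set(truth.index[truth["fold"] != 1.0])
selected = set(result.selected)
print(f"{len(selected)} of {len(result.table)} genes selected "
      f"(planted: {len(planted)}, recovered: {len(selected & planted)}, "
      f"false: {len(selected - planted)})")

profiles = np.log2(
    result.table.loc[result.selected, [c for c in result.table.columns if c.startswith("fold_")]]
)
profiles.columns = [c.removeprefix("fold_") for c in profiles.columns]
cluster = hierarchical_cluster(profiles)
print("first 5 genes in dendrogram order:", ", ".join(map(str, cluster.order[:5])))

# Selection requires p < 0.05 in the 4-replicate t-test AND a >= 2.5-fold
# change (either direction) in at least one of the five surface
# conditions; clustering groups genes with similar condition profiles.
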