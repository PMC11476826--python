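"""Hierarchical clustering of simulated samples on panel genes.

Correlation distance (1 - Pearson r on panel-restricted log-TPM) with
average linkage; lots of the same cell type should merge into tight,
type-pure neighborhoods.
"""

from panelqc import (
    SimConfig,
    distance_matrix,
    hierarchical_cluster,
    nearest_neighbors,
    simulate_dataset,
    to_newick,
)
from panelqc.pipeline import preprocess_counts

result = simulate_dataset(SimConfig(seed=3))
log = preprocess_counts(result.counts)

dist = distance_matrix(log, result.panel)
print("closest and farthest sample pairs (correlation distance):")
stacked = dist.where(~(dist == 0)).stack().sort_values()
print(f"  closest : {stacked.index[0]}  d={stacked.iloc[0]:.4f}")
print(f"  farthest: {stacked.index[-1]}  d={stacked.iloc[-1]:.4f}\n")

nn = nearest_neighbors(dist)
meta = result.counts.sample_meta
pure = sum(
    meta.loc[nn[s], "cell_type"] == meta.loc[s, "cell_type"]
    for s in meta.index if (meta.cell_type == meta.loc[s, "cell_type"]).sum() > 1
)
multi = sum((meta.cell_type == meta.loc[s, "cell_type"]).sum() > 1 for s in meta.index)
print(f"same-type nearest neighbors: {pure}/{multi} multi-lot samples\n")

dend = hierarchical_cluster(dist)
print("Newick dendrogram (branch lengths = merge height / 2):")
print(to_newick(dend))
# Each cell type's lots should be each other's nearest neighbors, the
# computable analogue of type-pure clades in a clustered heatmap.
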