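"""Expression-based consensus subtyping with NMF rank selection.

A planted 3-cluster expression matrix (100 marker genes per cluster shifted
by 2 log2 units) is normalized to mean 100 per array, filtered (max >= 100,
mean >= 10, CV >= 0.3), and subtyped by consensus k-means: for each k, 100
k-means runs on random 3000-gene subsets; samples that repeatedly co-cluster
define the consensus.  The candidate k whose consensus matrix factorizes
best at rank k (lowest relative Frobenius NMF error) is chosen.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from armcna.expression import (consensus_kmeans, filter_probes,
                               global_normalize, rank_marker_genes,
                               select_k_nmf)
from armcna.simulate import SimulationConfig, simulate_expression

config = SimulationConfig(seed=1)
labels = pd.Series([1 + i % 3 for i in range(30)],
                   index=[f"S{i:02d}" for i in range(30)])
sim = simulate_expression(labels, config)

filtered = filter_probes(global_normalize(sim.matrix))
print(f"{len(filtered)} of {len(sim.matrix)} probes pass the filter")

cons = consensus_kmeans(filtered, range(2, 11), n_iter=100, n_genes=3000, seed=2)
cons = select_k_nmf(cons, seed=3)
print("NMF error by k:",
      {k: round(v, 3) for k, v in sorted(cons.nmf_error.items())})
print(f"chosen k = {cons.chosen_k} (planted 3)")
ari = adjusted_rand_score(labels, cons.labels[cons.chosen_k])
print(f"agreement with planted labels: ARI = {ari:.2f}")

ranking = rank_marker_genes(filtered, cons.labels[cons.chosen_k], 1, 2)
top = ranking.head(5)
print("\ntop genes up in cluster 1 vs 2 (log2 fold change):")
print(top.to_string(index=False))
print()
print("An ARI of 1 means the consensus labels match the planted subtypes")
print("exactly; the NMF error dips at the true cluster number.")
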