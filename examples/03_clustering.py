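"""Cluster a planted-block dataset with the MST-kNN partitioning method.

Five blocks of 30 log-normal features over 17 samples; the algorithm
builds a connected q-NN graph, takes a deterministic MST, annotates
each edge with its mutual nearest-neighbour rank p, and recursively
removes weakly supported edges (criteria C1/C2/C3).
"""

from mstknn import adjusted_rand_index, cluster, planted_expression

ds = planted_expression(n_blocks=5, features_per_block=30, n_samples=17,
                        rho_within=0.9, noise_sd=0.3, seed=0)
result = cluster(ds.X)

print(f"{ds.X.shape[0]} features -> {result.n_clusters} clusters")
ari = adjusted_rand_index(result.assignment, ds.labels)
print(f"adjusted Rand index vs planted blocks: {ari:.3f}")
print("first split decisions (component size, criterion, edges removed):")
for entry in result.split_log[:6]:
    print("  ", entry)
print("A C1 entry removes edges whose endpoints are not within each "
      "other's t nearest neighbours (t = floor(ln n)); MINSIZE stops "
      "components of <= 3 nodes.")
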