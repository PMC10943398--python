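"""Consensus subtyping of case samples on the key-gene submatrix.

Cases carry a planted two-subcluster structure in the key genes; repeated
subsampled clustering scores every candidate k by the stability of its
consensus matrix, and the winning partition is contrasted gene by gene.
"""

from sklearn.metrics import adjusted_rand_score

from cuprosep import consensus_cluster, simulate_cohort, subcluster_contrast

cohort, truth = simulate_cohort(
    n_case=60, n_control=30, n_genes=500, de_fraction=0.05, lfc_mean=1.0,
    batch_count=1, batch_sd=0.0, noise_sd=0.5, seed=5, n_key=6,
)
cases = cohort.cases()
key = sorted(truth.key_genes)

res = consensus_cluster(cases.values[key], k_range=range(2, 7), H=100, p_item=0.8, seed=5)
ari = adjusted_rand_score(truth.subcluster_labels.values, res.labels.values)

print(f"chosen k:       {res.chosen_k}")
print(f"cluster sizes:  {res.labels.value_counts().sort_index().tolist()}")
print(f"ARI vs truth:   {ari:.2f}")
print(f"PAC by k:       { {k: round(v, 3) for k, v in res.pac.items()} }")
contrast = subcluster_contrast(cases.values, res.labels, key)
print(f"key genes with BH p < 0.01 between subclusters: {(contrast['p_adj'] < 0.01).sum()} of {len(key)}")
# PAC (proportion of ambiguous consensus values) is lowest at the stable k;
# an ARI of 1 means the planted subclusters were recovered exactly.
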