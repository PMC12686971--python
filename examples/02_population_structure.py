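"""Population structure: PCA, cluster number selection, DAPC and an
F_ST neighbour-joining tree with bootstrap supports.

Run: python examples/02_population_structure.py
"""

import numpy as np

from invpopgen.clustering import (
    bootstrap_supports,
    dapc,
    find_clusters,
    optimal_n_pcs,
    pca,
)
from invpopgen.synthetic import SyntheticScenario, generate_structured_genotypes

scenario = SyntheticScenario(
    n_demes=6,
    deme_sizes=[12] * 6,
    cluster_map=[0, 0, 1, 1, 2, 2],
    target_fst_between=0.25,
    target_fst_within=0.03,
    n_loci=500,
    seed=5,
)
gm, meta = generate_structured_genotypes(scenario)

# PCA on mean-imputed, centred dosages.
res = pca(gm)
print("variance explained by PC1-3:",
      np.round(res.explained_variance_ratio[:3], 3))

# BIC over k-means solutions picks the number of clusters.
clusters = find_clusters(gm, k_max=8, seed=0)
print(f"\nBIC-selected K = {clusters.K}")
print("BIC curve:", {k: round(v, 1) for k, v in sorted(clusters.bic_curve.items())})

# DAPC on the inferred clusters, with the a-score choosing how many PCs
# to retain (too many PCs overfits the discriminant functions).
best_pcs, ascores = optimal_n_pcs(gm, clusters.hard_labels, seed=0)
fit = dapc(gm, clusters.hard_labels, n_pcs=best_pcs)
print(f"\nDAPC with {best_pcs} PCs (a-score {ascores[best_pcs]:.3f}): "
      f"self-assignment {fit.self_assignment:.2%}")

# Neighbour-joining tree on pairwise F_ST, with locus-bootstrap supports.
tree = bootstrap_supports(gm, meta, n_boot=100, seed=0)
print("\nNJ tree (bootstrap supports on internal bipartitions):")
print(tree.newick())
for bip, support in sorted(tree.supports.items(), key=lambda kv: -kv[1]):
    side = sorted(min(bip, key=len))
    print(f"  {support:5.1f}%  {side}")
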