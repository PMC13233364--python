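"""Chemometric modelling: PCA, clustering, OPLS-DA and permutation test.

Runs the exploratory and supervised multivariate models on the default
planted metabolome and validates the global OPLS-DA with a 200-label-
permutation test.
"""

import numpy as np
from scipy.cluster import hierarchy

from lipomet import PlantConfig, generate_untargeted
from lipomet.chemometrics import (
    opls_da,
    pca,
    permutation_test,
    preprocess,
    top_variable_clustering,
)

table, _ = generate_untargeted(PlantConfig(seed=1))
matrix = preprocess(table)  # log2(x+1), autoscaled columns

model = pca(matrix, 2)
print("PCA R2X per component:", np.round(model.r2x_per_component, 3))
d_mean = model.scores[[s.startswith("D") for s in model.sample_ids], 0].mean()
rest = model.scores[[not s.startswith("D") for s in model.sample_ids], 0].mean()
print(f"t[1] means: regime D {d_mean:.1f} vs others {rest:.1f} "
      "(the 500 MPa regime drives the first component)")

clust = top_variable_clustering(table, k=100)
cut = hierarchy.fcluster(clust["sample_linkage"], t=2, criterion="maxclust")
branches = {}
for s, g in zip(table.abundance.columns, cut):
    branches.setdefault(g, []).append(s)
print("\nTop-100-variance sample dendrogram, two main branches:")
for g, samples in branches.items():
    print(f"  branch {g}: {samples}")
# Holding-only samples (A/B) split from the pressure-treated ones (C/D).

labels = [s[0] for s in matrix.sample_ids]
om = opls_da(matrix, labels, n_orthogonal=1)
print(f"\nGlobal OPLS-DA: R2X={om.r2x_cum:.3f} R2Y={om.r2y_cum:.3f} Q2={om.q2_cum:.3f}")
print(f"mean(VIP^2) = {(om.vip ** 2).mean():.6f} (1 by construction)")

perm = permutation_test(matrix, labels, n_permutations=200, seed=2)
print(f"\nPermutation test (n=200): original Q2 {perm.original_q2:.3f} "
      f"exceeds all permuted ({perm.q2.max():.3f} max); "
      f"Q2 intercept {perm.q2_intercept:.3f} (negative supports validity)")
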