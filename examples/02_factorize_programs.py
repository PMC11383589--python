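"""Extract gene expression programs from one cell type by consensus NMF.

Simulates a single-cell-type cohort with 5 planted programs, selects the
rank with the weighted-subtrees stability metric, fits a consensus model,
and compares the recovered loadings with the planted ground truth.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from gepnet import SyntheticConfig, simulate_cohort
from gepnet.factorize import (consensus_model, prepare_matrix,
                              weighted_subtrees_rank_selection)

ds = simulate_cohort(SyntheticConfig(
    n_cell_types=1, genes_per_type=600, programs_per_type=5,
    cells_per_sample_per_type=80, overdispersion=0.0, activity_effect=0.0,
    seed=2,
))
cm = ds.counts["B"]
X, genes = prepare_matrix(cm, n_top_genes=600)

sel = weighted_subtrees_rank_selection(X, list(range(2, 9)), n_restarts=5,
                                       seed=0, max_iter=80, tol=1e-3)
print("weighted-subtrees metric by rank:")
for k in sel.k_grid:
    marker = " <- chosen" if k == sel.chosen_k else ""
    print(f"  k={k}: {sel.metric[k]:.2f}{marker}")
# The metric climbs while added programs are reproducible across restarts
# and plateaus at the planted rank.

model = consensus_model(X, sel.chosen_k, n_restarts=5, seed=0,
                        gene_ids=genes, cell_ids=cm.cell_ids, cell_type="B")
Wt = ds.truth.true_loadings["B"].loc[genes].to_numpy()
A = Wt / np.linalg.norm(Wt, axis=0)
B = model.W.to_numpy() / np.linalg.norm(model.W.to_numpy(), axis=0)
C = A.T @ B
r, c = linear_sum_assignment(-C)
print(f"\nmatched loading cosines vs planted programs: "
      f"{np.round(C[r, c], 3)}")
print(f"mean: {C[r, c].mean():.3f}  (1.0 = perfect recovery)")
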