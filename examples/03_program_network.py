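"""Build the cross-cell-type program network and detect modules.

Correlates per-sample program scores across programs, keeps positive
bootstrap-significant edges, and clusters the graph into modules by
modularity optimization.
"""

import numpy as np
import pandas as pd

from gepnet.network import build_network, correlate_programs, detect_modules

# per-sample scores for 12 programs in 3 planted modules (rho = 0.7)
rng = np.random.default_rng(3)
cols = {}
for m, ct in enumerate(["B", "CD4T", "NK"]):
    base = rng.standard_normal(30)
    for j in range(1, 5):
        cols[f"{ct}_p{j}"] = (np.sqrt(0.7) * base
                              + np.sqrt(0.3) * rng.standard_normal(30))
scores = pd.DataFrame(cols)

edges = correlate_programs(scores, n_boot=1000, seed=0)
net = build_network(edges, alpha=0.05)
modules = detect_modules(net, seed=0)

print(f"nodes: {len(net.nodes)}, retained edges: "
      f"{net.graph.number_of_edges()} "
      f"(positive Pearson with bootstrap p < 0.05)")
print("\nmodule assignment:")
for mod in sorted(set(modules.values())):
    members = sorted(n for n, m in modules.items() if m == mod)
    print(f"  module {mod}: {', '.join(members)}")
# Each planted module (one per cell type here) should come back as one
# detected community; edges across modules are rare because inter-module
# correlation is zero by construction.
mean_r = np.mean([d["r"] for _, _, d in net.graph.edges(data=True)])
print(f"\nmean retained edge correlation: {mean_r:.2f}")
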