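# gepnet

Coordinated cell-state analysis for multi-sample single-cell cohorts.

In autoimmune diseases such as juvenile dermatomyositis, dysregulation is
not confined to one cell type: a hyperactive type I interferon response in
every major immune population co-occurs with depressed translation and
cell-death programs in cytotoxic cells. Detecting that coordination requires
moving from per-cluster differential expression to *programs* — axes of
coordinated gene expression within a cell type — and asking how program
activity covaries **across patients**. `gepnet` implements that analysis
end to end for anyone with per-cell-type count matrices and a per-sample
clinical table.

## The method

For each cell type with counts $X \in \mathbb{N}^{g \times c}$ (top
overdispersed genes, cells depth-scaled), non-negative matrix factorization

$$X \approx W H, \qquad W \ge 0,\; H \ge 0$$

yields gene expression programs: loadings $W$ (gene × k, columns sum to 1)
and per-cell usages $H$ (k × cell). The rank $k$ is chosen by a stability
criterion ("weighted subtrees"): loading vectors from repeated fits on
resampled cells are pooled into a correlation-distance tree, reproducible
subtrees are scored by their mean intra-correlation, and $k$ is the
saturation point of that curve. A consensus model (median loading per
restart cluster, usages re-solved by NNLS) gives the reported factorization.

Per-sample program scores $s_{sp} = \mathrm{mean}_{c \in s} H_{pc}$ — after
removing programs dominated by a single sample — are correlated across all
program pairs (Pearson, one-sided bootstrap significance). Edges with
$r > 0$, $p < 0.05$ form the program network; Leiden modularity communities
are its modules. Gene-set themes per module come from preranked GSEA on
marker-score rankings plus a permutation test against size-matched random
node sets. Clinical structure is tested with Kruskal–Wallis/Dunn (cell-type
composition), Welch t (case vs control), four-group one-way ANOVA with
Tukey HSD (disease activity), and Spearman correlation against a 0–10
physician-global VAS. Signatures transfer to independent cohorts through a
per-cell rank-AUC of each program's top 5% marker genes — a rank statistic
that needs no normalization or refitting.

A synthetic cohort generator with planted programs, planted cross-cell-type
modules, a disease-activity covariate and a correlated surface-protein
(ADT) channel provides ground truth for every stage; its defaults mirror a
27-sample, four-group (HC/Inactive/Active/TreatmentNaive) pediatric cohort.

## Worked example

```python
import numpy as np
from scipy.optimize import linear_sum_assignment
from gepnet import SyntheticConfig, simulate_cohort
from gepnet.factorize import (prepare_matrix, consensus_model,
                              weighted_subtrees_rank_selection)

ds = simulate_cohort(SyntheticConfig(
    n_cell_types=1, genes_per_type=600, programs_per_type=5,
    cells_per_sample_per_type=80, overdispersion=0.0, activity_effect=0.0,
    seed=2))
X, genes = prepare_matrix(ds.counts["B"], n_top_genes=600)
sel = weighted_subtrees_rank_selection(X, range(2, 9), n_restarts=5, seed=0,
                                       max_iter=80, tol=1e-3)
```

The stability metric climbs while added programs reproduce across restarts
and plateaus at the planted rank:

```
weighted-subtrees metric by rank:
  k=2: 1.99
  k=3: 2.99
  k=4: 3.98
  k=5: 4.98 <- chosen
  k=6: 4.98
  k=7: 4.99
  k=8: 4.95
```

Fitting the consensus model at the chosen rank and matching recovered to
planted loadings (Hungarian assignment on cosine similarity):

```
matched loading cosines vs planted programs: [0.999 0.998 0.999 0.999 0.999]
mean: 0.999  (1.0 = perfect recovery)
```

Each cosine compares one recovered loading column with its best-matched
planted program; values near 1 mean the factorization found exactly the
planted gene programs. The `examples/` directory has one short script per
capability (cohort simulation, factorization, network + modules, clinical
association, proxy transfer); each prints the numbers above along with a
line on how to read them.

A thin CLI mirrors the stages:

```bash
gepnet simulate --config cohort.yaml --out cohort/ --seed 1
gepnet factorize --counts cohort/ --cell-type B --k-grid 5:20 --out out/
gepnet run --config pipeline.yaml --seed 1
```

On-disk formats are plain text throughout: Matrix Market MTX (genes ×
cells) with `features.tsv`/`barcodes.tsv` per cell type, CSV metadata and
clinical tables, GMT gene sets, TSV outputs with a JSON manifest recording
parameters, per-stage seeds and input checksums; reruns with the same
config and seed are byte-identical.

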