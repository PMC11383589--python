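"""Cross-cell-type program correlation networks and module statistics.

Nodes are (cell type, program) pairs; an edge connects two programs whose
per-sample mean usages are positively correlated (Pearson) with bootstrap
support. Modules are communities found by modularity optimization on the
r-weighted graph. Module-level gene-set themes are scored by a permutation
test against size-matched random node sets, and within-module program pairs
can be compared by gene-loading similarity (permutation p) and top-gene
overlap (Fisher's exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_FDR_FLOOR = 1e-10  # floor before -log10 so degenerate FDRs stay finite


@dataclass
class ProgramNetwork:
    """Program correlation network with module labels."""

    graph: nx.Graph                    # nodes carry 'cell_type'; edges r, p
    module_of: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["r"], d["p"],
             self.module_of.get(a), self.module_of.get(b))
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "r", "p", "module_a", "module_b"]
        )

    def module_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.module_of.items()), columns=["node", "module"]
        )


def correlate_programs(scores: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0, min_common: int = 5) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-sample program scores with
    one-sided bootstrap significance for positive association.

    ``scores`` is sample x program (columns may span cell types; NaN where a
    sample was dropped for a cell type). For each pair with at least
    ``min_common`` common samples, r is the Pearson correlation over common
    samples and ``p = (1 + #{b : r_b <= 0}) / (n_boot + 1)`` from resampling
    samples with replacement. Pairs with fewer common samples or a constant
    column are marked missing (NaN) and logged. Returns a long frame
    (prog_a, prog_b, r, p, n_samples) over unordered pairs.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    rng = np.random.default_rng(seed)
    cols = list(scores.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = scores[cols[i]].to_numpy(dtype=float)
            b = scores[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            n = int(ok.sum())
            if n < min_common:
                log.warning("pair (%s, %s): only %d common samples; skipped",
                            cols[i], cols[j], n)
                rows.append((cols[i], cols[j], np.nan, np.nan, n))
                continue
            x, y = a[ok], b[ok]
            if np.std(x) == 0 or np.std(y) == 0:
                log.warning("pair (%s, %s): constant column; r undefined",
                            cols[i], cols[j])
                rows.append((cols[i], cols[j], np.nan, np.nan, n))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            idx = rng.integers(0, n, size=(n_boot, n))
            xb, yb = x[idx], y[idx]
            xc = xb - xb.mean(axis=1, keepdims=True)
            yc = yb - yb.mean(axis=1, keepdims=True)
            num = (xc * yc).sum(axis=1)
            den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            rb = np.divide(num, den, out=np.zeros(n_boot), where=den > 0)
            p = (1.0 + np.sum(rb <= 0.0)) / (n_boot + 1.0)
            rows.append((cols[i], cols[j], r, p, n))
    return pd.DataFrame(rows, columns=["prog_a", "prog_b", "r", "p", "n_samples"])


def build_network(edge_stats: pd.DataFrame, alpha: float = 0.05,
                  cell_type_of=None, layout_seed: int = 0) -> ProgramNetwork:
    """Keep edges with r > 0 and p < alpha; isolated nodes retained.

    ``cell_type_of`` optionally maps node label -> cell type; by default the
    prefix before the final ``_p<k>`` suffix is used. A seeded force-directed
    layout is attached for reporting only.
    """
    g = nx.Graph()
    nodes = sorted(set(edge_stats["prog_a"]) | set(edge_stats["prog_b"]))
    for nd in nodes:
        ct = (cell_type_of(nd) if callable(cell_type_of)
              else nd.rsplit("_p", 1)[0])
        g.add_node(nd, cell_type=ct)
    for _, row in edge_stats.iterrows():
        if np.isnan(row["r"]):
            continue
        if row["r"] > 0 and row["p"] < alpha:
            g.add_edge(row["prog_a"], row["prog_b"],
                       r=float(row["r"]), p=float(row["p"]))
    isolated = [nd for nd in g.nodes if g.degree(nd) == 0]
    if isolated:
        log.info("%d isolated nodes retained: %s", len(isolated), isolated[:8])
    layout = nx.spring_layout(g, seed=layout_seed) if len(g) else {}
    return ProgramNetwork(graph=g, module_of={},
                          layout={k: tuple(v) for k, v in layout.items()})


def detect_modules(network: ProgramNetwork, seed: int = 0) -> dict:
    """Assign modules by modularity optimization on the r-weighted graph.

    Seeded Leiden partition; singleton (edgeless) nodes each get their own
    module. Module ids are contiguous from 1, ordered by descending size then
    lexicographically smallest member. The assignment is stored on the
    network and returned.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    edges = [(a, b) for a, b in g.edges]
    if not edges:
        log.warning("edgeless network: every node becomes its own module")
        network.module_of = {nd: i + 1 for i, nd in enumerate(nodes)}
        return network.module_of
    index = {nd: i for i, nd in enumerate(nodes)}
    ig = igraph.Graph(
        n=len(nodes),
        edges=[(index[a], index[b]) for a, b in edges],
    )
    weights = [float(g.edges[a, b]["r"]) for a, b in edges]
    part = leidenalg.find_partition(
        ig, leidenalg.ModularityVertexPartition,
        weights=weights, seed=seed, n_iterations=-1,
    )
    raw = {nodes[v]: cid for cid, comm in enumerate(part) for v in comm}
    groups = {}
    for nd, cid in raw.items():
        groups.setdefault(cid, []).append(nd)
    ordered = sorted(groups.values(), key=lambda mem: (-len(mem), min(mem)))
    module_of = {nd: mid for mid, mem in enumerate(ordered, start=1)
                 for nd in mem}
    network.module_of = module_of
    return module_of


def module_enrichment_pvalues(network: ProgramNetwork,
                              gsea_table: pd.DataFrame,
                              n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Permutation p-values for module-level gene-set themes.

    ``gsea_table`` holds per-(program, gene set) FDR values (columns
    ``program``, ``gene_set``, ``fdr``). The statistic for module M and set g
    is the mean over M's programs of -log10(max(FDR, 1e-10)); the null draws
    ``n_perm`` random node subsets of size |M| from the whole network.
    p = (1 + #{T_perm >= T_obs}) / (n_perm + 1), BH-adjusted across gene sets
    within each module. Modules of size 1 are computed but flagged.
    """
    if not network.module_of:
        raise ValueError("network has no module assignment; run detect_modules")
    fdr = gsea_table.pivot_table(index="program", columns="gene_set",
                                 values="fdr")
    nodes = [nd for nd in network.nodes if nd in fdr.index]
    if not nodes:
        raise ValueError("no network node has gene-set results")
    neglog = -np.log10(np.maximum(fdr.loc[nodes].to_numpy(dtype=float),
                                  _FDR_FLOOR))
    node_idx = {nd: i for i, nd in enumerate(nodes)}
    sets = list(fdr.columns)
    rng = np.random.default_rng(seed)
    rows = []
    modules = sorted(set(network.module_of.values()))
    for m in modules:
        members = [nd for nd, mm in network.module_of.items()
                   if mm == m and nd in node_idx]
        if not members:
            continue
        size = len(members)
        low_power = size == 1
        if low_power:
            log.warning("module %d has a single scored program; low power", m)
        obs = neglog[[node_idx[nd] for nd in members]].mean(axis=0)
        perm_idx = np.array([
            rng.choice(len(nodes), size=size, replace=False)
            for _ in range(n_perm)
        ])
        null = neglog[perm_idx].mean(axis=1)      # n_perm x n_sets
        pvals = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
        adj = _bh(pvals)
        for s, p, q, t in zip(sets, pvals, adj, obs):
            rows.append((m, s, size, t, p, q, low_power))
    return pd.DataFrame(
        rows, columns=["module", "gene_set", "module_size", "statistic",
                       "p", "p_adj", "low_power"],
    )


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def gene_loading_similarity(model_a, model_b, pairs, n_perm: int = 999,
                            seed: int = 0, min_shared: int = 100) -> pd.DataFrame:
    """Pearson similarity of gene-loading vectors with permutation p-values.

    ``pairs`` lists (program_of_a, program_of_b) label pairs (typically
    within one module). Loadings are restricted to the intersection of the
    two models' gene subsets (at least ``min_shared`` genes), and
    p = (1 + #{perm : r_perm >= r_obs}) / (n_perm + 1) from permuting one
    vector's gene labels.
    """
    shared = sorted(set(model_a.W.index) & set(model_b.W.index))
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared genes between models "
            f"(need >= {min_shared}); gene subsets may not overlap"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for pa, pb in pairs:
        x = model_a.W.loc[shared, pa].to_numpy(dtype=float)
        y = model_b.W.loc[shared, pb].to_numpy(dtype=float)
        r = float(np.corrcoef(x, y)[0, 1])
        perm_r = np.empty(n_perm)
        for b in range(n_perm):
            perm_r[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p = (1.0 + np.sum(perm_r >= r)) / (n_perm + 1.0)
        rows.append((pa, pb, r, p, len(shared)))
    return pd.DataFrame(
        rows, columns=["prog_a", "prog_b", "pearson_r", "p", "n_shared_genes"]
    )


def gene_overlap_fisher(top_genes_a, top_genes_b, universe):
    """One-sided (enrichment) Fisher's exact test for top-gene overlap.

    Returns (odds_ratio, p) for the 2x2 table of membership in the two gene
    sets over the stated universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a, b = set(top_genes_a), set(top_genes_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                                 alternative="greater")
    return float(odds), float(p)
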