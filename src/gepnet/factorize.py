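"""Per-cell-type gene expression program (GEP) extraction.

Programs are extracted by nonnegative matrix factorization (NMF) of the raw
count matrix after selection of overdispersed genes and per-cell depth
scaling. The NMF rank is chosen by a stability criterion ("weighted
subtrees"): loading vectors from repeated seeded restarts are pooled into a
correlation-distance tree, and the metric for a candidate rank sums the mean
intra-correlation of maximal subtrees that are reproduced across most
restarts; the chosen rank is the saturation point of that curve. A consensus
model is then built from the restart clusters, marker-gene scores rank genes
by program specificity, per-sample program scores average usages within each
sample, and programs dominated by a single sample are filtered out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .containers import CountMatrix

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class GEPModel:
    """An NMF decomposition X ~ W H for one cell type.

    W is gene x k with columns summing to 1 (usages rescaled so W H is
    unchanged by the renormalization); H is k x cell, nonnegative.
    """

    W: pd.DataFrame            # gene x program
    H: pd.DataFrame            # program x cell
    k: int
    objective_trace: list
    cell_type: str = ""
    gene_subset: list = field(default_factory=list)
    consensus_fallback: bool = False

    @property
    def program_ids(self) -> list:
        return list(self.W.columns)


@dataclass
class RankSelectionResult:
    k_grid: list
    metric: dict               # k -> weighted-subtrees score
    chosen_k: int
    restarts: int


# --------------------------------------------------------------------------
# preprocessing


def prepare_matrix(counts: CountMatrix, n_top_genes: int = 2000):
    """Select overdispersed genes and depth-scale cells.

    Genes are ranked by their variance-to-mean ratio (Fano factor) computed
    on raw counts, ties broken by gene id; the ``n_top_genes`` highest are
    kept and each cell is rescaled so its total over the kept genes is
    10,000. Returns ``(X, gene_subset)`` with X dense float64 gene x cell.
    """
    X = counts.values
    if X.nnz == 0:
        raise ValueError("all-zero count matrix")
    if n_top_genes > counts.n_genes:
        raise ValueError(
            f"n_top_genes={n_top_genes} exceeds {counts.n_genes} genes"
        )
    Xi = sp.csr_matrix(X, dtype=np.int64)
    n_cells = counts.n_cells
    sums = np.asarray(Xi.sum(axis=1)).ravel()
    sumsq = np.asarray(Xi.multiply(Xi).sum(axis=1)).ravel()
    # n^2 * var / (n * mean): integer numerator keeps zero-variance ties exact
    num = n_cells * sumsq - sums**2
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(sums > 0, num / (n_cells * sums), 0.0)
    Xc = sp.csr_matrix(X, dtype=np.float64)
    order = sorted(range(counts.n_genes),
                   key=lambda i: (-fano[i], counts.gene_ids[i]))
    keep = sorted(order[:n_top_genes])
    gene_subset = [counts.gene_ids[i] for i in keep]
    M = np.asarray(Xc[keep, :].todense())
    tot = M.sum(axis=0)
    scale = np.where(tot > 0, 1e4 / np.maximum(tot, _EPS), 0.0)
    return M * scale[None, :], gene_subset


# --------------------------------------------------------------------------
# NMF core (multiplicative updates, Frobenius objective)


def _frobenius_objective(sq_norm_X, W, H, XHt):
    # ||X - WH||^2 = ||X||^2 - 2 tr(W' X H') + tr(W'W HH')
    WtW = (W.T @ W).astype(np.float64)
    HHt = (H @ H.T).astype(np.float64)
    cross = float(np.einsum("ij,ij->", W, XHt, dtype=np.float64))
    return float(sq_norm_X - 2.0 * cross + np.sum(WtW * HHt))


def _mu_fit(X, k, rng, max_iter, tol, check_every=10, W=None, update_W=True):
    """Multiplicative-update NMF minimizing ||X - WH||_F^2.

    Returns (W, H, trace). The trace records the objective at initialization
    and at every convergence check; MU updates guarantee it is nonincreasing.
    """
    n, m = X.shape
    dtype = X.dtype if X.dtype in (np.float32, np.float64) else np.float64
    scale = math.sqrt(max(X.mean(), _EPS) / k)
    if W is None:
        W = (scale * rng.random((n, k)) + _EPS).astype(dtype)
    else:
        W = np.maximum(np.asarray(W, dtype=dtype), _EPS).copy()
    H = (scale * rng.random((k, m)) + _EPS).astype(dtype)
    sq_norm_X = float(np.einsum("ij,ij->", X, X, dtype=np.float64))
    XHt = X @ H.T
    trace = [_frobenius_objective(sq_norm_X, W, H, XHt)]
    prev = trace[0]
    for it in range(1, max_iter + 1):
        # H update
        WtX = W.T @ X
        WtW = W.T @ W
        H *= WtX / np.maximum(WtW @ H, _EPS)
        if update_W:
            XHt = X @ H.T
            HHt = H @ H.T
            W *= XHt / np.maximum(W @ HHt, _EPS)
        if it % check_every == 0 or it == max_iter:
            if update_W:
                XHt = X @ H.T  # W changed since XHt was formed
            else:
                XHt = X @ H.T
            obj = _frobenius_objective(sq_norm_X, W, H, XHt)
            trace.append(obj)
            if prev > 0 and (prev - obj) / prev < tol:
                break
            prev = obj
    return W, H, trace


def _normalize_model(W, H):
    """Rescale so W columns sum to 1, compensating in H (WH unchanged)."""
    colsum = W.sum(axis=0)
    colsum = np.maximum(colsum, _EPS)
    return W / colsum[None, :], H * colsum[:, None]


def fit_nmf(X, k: int, seed: int, max_iter: int = 300, tol: float = 1e-5,
            gene_ids=None, cell_ids=None, cell_type: str = "") -> GEPModel:
    """Fit a single seeded NMF model to a nonnegative matrix.

    Stops when the relative decrease of the Frobenius objective between
    convergence checks falls below ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("NaN in input matrix")
    if (X < 0).any():
        raise ValueError("negative entries in input matrix")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"rank k={k} outside [1, {min(X.shape)}]")
    rng = np.random.default_rng(seed)
    W, H, trace = _mu_fit(X, k, rng, max_iter, tol)
    W, H = _normalize_model(W, H)
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"g{i}" for i in range(X.shape[0])
    ]
    cell_ids = list(cell_ids) if cell_ids is not None else [
        f"c{i}" for i in range(X.shape[1])
    ]
    progs = [f"{cell_type or 'X'}_p{j+1}" for j in range(k)]
    return GEPModel(
        W=pd.DataFrame(W, index=gene_ids, columns=progs),
        H=pd.DataFrame(H, index=progs, columns=cell_ids),
        k=k,
        objective_trace=trace,
        cell_type=cell_type,
        gene_subset=gene_ids,
    )


# --------------------------------------------------------------------------
# weighted-subtrees rank selection


def _restart_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _pooled_loadings(X, k, n_restarts, seed, max_iter, tol,
                     subsample_frac: float = 0.8):
    """Column-normalized loading vectors from n_restarts seeded fits,
    annotated with the restart each came from.

    Each restart fits a random ``subsample_frac`` of the cells (plus a fresh
    random init), so programs that only encode noise in the full matrix fail
    to reproduce across restarts while genuine programs persist.
    """
    cols, restart_of, objs = [], [], []
    m = X.shape[1]
    n_sub = max(k, int(round(subsample_frac * m)))
    for r, sd in enumerate(_restart_seeds(seed, n_restarts)):
        rng = np.random.default_rng(sd)
        if n_sub < m:
            keep = rng.choice(m, size=n_sub, replace=False)
            Xr = np.ascontiguousarray(X[:, keep])
        else:
            Xr = X
        W, H, trace = _mu_fit(Xr, k, rng, max_iter, tol)
        W, _ = _normalize_model(W, H)
        for j in range(k):
            cols.append(W[:, j])
            restart_of.append(r)
        objs.append(trace[-1])
    return np.array(cols).T, np.array(restart_of), objs


def _subtree_members(Z, n_leaves):
    """Leaf sets of every internal node of a scipy linkage matrix."""
    members = {i: [i] for i in range(n_leaves)}
    for i, row in enumerate(Z):
        a, b = int(row[0]), int(row[1])
        members[n_leaves + i] = members[a] + members[b]
    return members


def _weighted_subtrees_score(L, restart_of, n_restarts,
                             min_corr: float = 0.8,
                             restart_frac: float = 0.8):
    """Sum of mean intra-correlations over maximal reproducible subtrees.

    A subtree qualifies if its loading vectors come from at least
    ceil(restart_frac * n_restarts) distinct restarts and their mean pairwise
    Pearson correlation is >= min_corr; only subtrees not contained in a
    larger qualifying subtree contribute.
    """
    n = L.shape[1]
    if n < 2:
        return 0.0
    C = np.corrcoef(L.T)
    C = np.nan_to_num(C, nan=0.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(np.maximum(D, 0.0), checks=False), method="average")
    members = _subtree_members(Z, n)
    need = math.ceil(restart_frac * n_restarts)
    qualifying = {}
    for node in range(n, n + len(Z)):
        mem = members[node]
        if len(set(restart_of[mem])) < need:
            continue
        sub = C[np.ix_(mem, mem)]
        iu = np.triu_indices(len(mem), 1)
        mean_r = float(sub[iu].mean())
        if mean_r >= min_corr:
            qualifying[node] = (frozenset(mem), mean_r)
    # one subtree per reproducible program: keep the finest qualifying nodes
    # (a qualifying parent joining two tight qualifying clusters represents
    # two programs, so the children are counted, not the union)
    score = 0.0
    for node, (mem, mean_r) in qualifying.items():
        has_finer = any(
            omem < mem for other, (omem, _) in qualifying.items()
            if other != node
        )
        if not has_finer:
            score += mean_r
    return score


def weighted_subtrees_rank_selection(
    X, k_grid, n_restarts: int = 5, seed: int = 0,
    max_iter: int = 150, tol: float = 1e-4,
    min_corr: float = 0.8, restart_frac: float = 0.8,
    saturation: float = 0.05,
) -> RankSelectionResult:
    """Choose the NMF rank by the stability of restart-pooled loading trees.

    The metric tends to grow while added programs are reproducible and to
    plateau (saturate) at the underlying program count; the chosen rank is
    the last grid point whose relative gain over its predecessor is at least
    ``saturation`` (the saturation point of the elbow curve), or the argmax
    if the curve never saturates.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k_grid")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    if n_restarts < 3:
        raise ValueError("need n_restarts >= 3")
    # exploration fits: single precision is ample for loading-correlation trees
    X = np.asarray(X, dtype=np.float32)
    metric = {}
    for i, k in enumerate(k_grid):
        L, restart_of, _ = _pooled_loadings(
            X, k, n_restarts, seed + 1000 * i, max_iter, tol
        )
        metric[k] = _weighted_subtrees_score(
            L, restart_of, n_restarts, min_corr, restart_frac
        )
        log.info("weighted subtrees: k=%d score=%.4f", k, metric[k])
    ks = k_grid
    if len(ks) == 1:
        chosen = ks[0]
    else:
        # saturation point: the first k at the curve's running peak after
        # which the metric stops rising (no point in the lookahead window
        # gains more than `saturation` relative to it). Dips below the true
        # rank reflect unstable under-factorization and are skipped because
        # the curve later rises above them.
        lookahead = 2
        chosen = None
        running_max = -np.inf
        for i in range(len(ks) - 1):
            cur = metric[ks[i]]
            if cur < running_max:
                continue
            running_max = cur
            nxt = [metric[k] for k in ks[i + 1 : i + 1 + lookahead]]
            ceiling = cur + saturation * max(abs(cur), _EPS)
            if max(nxt) <= ceiling:
                chosen = ks[i]
                break
        if chosen is None:
            chosen = max(ks, key=lambda k: metric[k])
    return RankSelectionResult(k_grid=ks, metric=metric, chosen_k=chosen,
                               restarts=n_restarts)


# --------------------------------------------------------------------------
# consensus model


def consensus_model(X, chosen_k: int, n_restarts: int = 5, seed: int = 0,
                    max_iter: int = 300, tol: float = 1e-5,
                    gene_ids=None, cell_ids=None,
                    cell_type: str = "") -> GEPModel:
    """Stabilized factorization at the chosen rank.

    Pools loading vectors from ``n_restarts`` seeded fits, clusters them into
    ``chosen_k`` groups on the same correlation-distance average-linkage tree
    used for rank selection, takes each group's median loading as the
    consensus W, and solves for nonnegative H by per-cell nonnegative least
    squares. Falls back to the best-objective single restart (flagged) if
    clustering does not produce ``chosen_k`` nonempty groups.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_restarts == 1:
        return fit_nmf(X, chosen_k, seed=seed, max_iter=max_iter, tol=tol,
                       gene_ids=gene_ids, cell_ids=cell_ids,
                       cell_type=cell_type)
    L, restart_of, objs = _pooled_loadings(
        X, chosen_k, n_restarts, seed, max_iter, tol
    )
    fallback = False
    W = None
    if chosen_k == 1:
        W = np.median(L, axis=1, keepdims=True)
    else:
        C = np.nan_to_num(np.corrcoef(L.T), nan=0.0)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(np.maximum(D, 0.0), checks=False),
                    method="average")
        labels = fcluster(Z, t=chosen_k, criterion="maxclust")
        if len(set(labels)) == chosen_k:
            W = np.column_stack([
                np.median(L[:, labels == g], axis=1)
                for g in sorted(set(labels))
            ])
        else:
            fallback = True
    if fallback:
        log.warning("consensus clustering yielded < k groups; "
                    "falling back to best single restart")
        best = int(np.argmin(objs))
        sd = _restart_seeds(seed, n_restarts)[best]
        model = fit_nmf(X, chosen_k, seed=sd, max_iter=max_iter, tol=tol,
                        gene_ids=gene_ids, cell_ids=cell_ids,
                        cell_type=cell_type)
        model.consensus_fallback = True
        return model
    W = W / np.maximum(W.sum(axis=0), _EPS)[None, :]
    # nonnegative least squares for H, cell by cell
    m = X.shape[1]
    H = np.empty((chosen_k, m))
    for c in range(m):
        H[:, c], _ = nnls(W, X[:, c])
    sq_norm_X = float(np.sum(X * X))
    obj = _frobenius_objective(sq_norm_X, W, H, X @ H.T)
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"g{i}" for i in range(X.shape[0])
    ]
    cell_ids = list(cell_ids) if cell_ids is not None else [
        f"c{i}" for i in range(X.shape[1])
    ]
    progs = [f"{cell_type or 'X'}_p{j+1}" for j in range(chosen_k)]
    return GEPModel(
        W=pd.DataFrame(W, index=gene_ids, columns=progs),
        H=pd.DataFrame(H, index=progs, columns=cell_ids),
        k=chosen_k,
        objective_trace=[obj],
        cell_type=cell_type,
        gene_subset=gene_ids,
    )


# --------------------------------------------------------------------------
# marker scores, sample scores, outlier filtering


def marker_scores(model: GEPModel) -> pd.DataFrame:
    """Specificity-weighted gene rankings per program.

    With column-normalized loadings, the marker score of gene g in program p
    is the z-score of W[g, p] across the k programs for that gene multiplied
    by the gene's normalized loading in p. For k = 1 specificity is
    undefined; the raw normalized loadings are returned (flagged via the
    ``degenerate`` column). Long-format frame: gene, program, marker_score,
    rank (per-program descending, ties by gene id).
    """
    W = model.W.to_numpy()
    genes = list(model.W.index)
    progs = list(model.W.columns)
    k = W.shape[1]
    degenerate = k == 1
    if degenerate:
        score = W.copy()
    else:
        mu = W.mean(axis=1, keepdims=True)
        sd = W.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 0, (W - mu) / np.maximum(sd, _EPS), 0.0)
        score = z * W
    rows = []
    for j, p in enumerate(progs):
        order = sorted(range(len(genes)), key=lambda i: (-score[i, j], genes[i]))
        rank = np.empty(len(genes), dtype=int)
        for r, i in enumerate(order, start=1):
            rank[i] = r
        for i, g in enumerate(genes):
            rows.append((g, p, score[i, j], rank[i], degenerate))
    return pd.DataFrame(
        rows, columns=["gene", "program", "marker_score", "rank", "degenerate"]
    )


def sample_program_scores(model: GEPModel, cell_metadata: pd.DataFrame,
                          min_cells: int = 10) -> pd.DataFrame:
    """Per-sample mean usage for each program of one cell type.

    ``cell_metadata`` must map every cell id in ``model.H`` to a sample via
    columns ``barcode`` and ``sample_id``. Samples contributing fewer than
    ``min_cells`` cells are dropped (logged). Returns sample x program frame
    with the contributing cell count in attrs["n_cells"].
    """
    meta = cell_metadata.set_index("barcode")
    missing = [c for c in model.H.columns if c not in meta.index]
    if missing:
        raise ValueError(f"cells missing from metadata: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    sample_of = meta.loc[list(model.H.columns), "sample_id"]
    scores = model.H.T.groupby(sample_of.to_numpy()).mean()
    n_cells = sample_of.value_counts()
    keep = n_cells[n_cells >= min_cells].index
    dropped = sorted(set(scores.index) - set(keep))
    if dropped:
        log.warning("dropping samples with < %d cells: %s", min_cells, dropped)
    scores = scores.loc[sorted(keep)]
    scores.index.name = "sample_id"
    scores.attrs["n_cells"] = n_cells.to_dict()
    return scores


def filter_outlier_programs(scores: pd.DataFrame,
                            max_sample_share: float = 0.5,
                            min_active_samples: int = 3):
    """Drop programs dominated by one sample or active in too few samples.

    A program is removed if a single sample carries more than
    ``max_sample_share`` of its total score mass, or if fewer than
    ``min_active_samples`` samples score above 10% of the program's maximum.
    Returns ``(retained_ids, report)`` with a per-program rule report.
    """
    if scores.empty:
        raise ValueError("empty score matrix")
    retained, rows = [], []
    for p in scores.columns:
        col = scores[p].to_numpy(dtype=float)
        total = col.sum()
        share = float(col.max() / total) if total > 0 else 1.0
        active = int((col > 0.1 * col.max()).sum()) if col.max() > 0 else 0
        rule = None
        if share > max_sample_share:
            rule = "single_sample_dominated"
        elif active < min_active_samples:
            rule = "too_few_active_samples"
        else:
            retained.append(p)
        rows.append((p, share, active, rule if rule else "retained"))
    if not retained:
        log.warning("outlier filtering removed every program")
    report = pd.DataFrame(
        rows, columns=["program", "max_sample_share", "n_active_samples", "rule"]
    )
    return retained, report
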