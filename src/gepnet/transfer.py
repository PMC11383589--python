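"""Signature transfer to independent cohorts via rank-AUC proxy scores.

A program's top marker genes (default: top 5% by marker score) form a proxy
gene set. In a new dataset each cell is scored by the area under the set's
recovery curve within the top-ranked fraction of that cell's expression
profile — a rank-based statistic invariant to monotone normalization.
Pseudobulk (per-sample mean) proxy scores then support the same
case/control and disease-activity statistics as the original NMF scores.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, CountMatrix

log = logging.getLogger(__name__)


def top_markers(marker_table: pd.DataFrame, fraction: float = 0.05) -> list:
    """Top ``ceil(fraction * n_genes)`` genes of one program by marker score.

    ``marker_table`` is the long frame of one program (columns ``gene``,
    ``marker_score``). Ties are broken by ascending gene id, so the
    lexicographically smaller gene wins at the cutoff.
    """
    if marker_table.empty:
        raise ValueError("empty marker table")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    tab = marker_table.sort_values(
        ["marker_score", "gene"], ascending=[False, True], kind="stable"
    )
    n = math.ceil(fraction * len(tab))
    return list(tab["gene"].head(n))


def rank_auc_score(expression, gene_set, top_fraction: float = 0.05,
                   gene_ids=None, cell_ids=None) -> pd.Series:
    """Per-cell AUC of the gene-set recovery curve in the top-ranked genes.

    For each cell, genes are ranked by descending expression (ties broken by
    ascending gene id); the recovery curve counts set genes among the first
    ``ceil(top_fraction * n_genes)`` ranks, and the AUC is normalized by the
    maximum possible area (all set genes at the very top). Values are in
    [0, 1]; the statistic depends on ranks only.
    """
    if isinstance(expression, CountMatrix):
        X = np.asarray(expression.values.todense(), dtype=float)
        gene_ids = expression.gene_ids
        cell_ids = expression.cell_ids
    elif isinstance(expression, pd.DataFrame):
        X = expression.to_numpy(dtype=float)
        gene_ids = list(expression.index)
        cell_ids = list(expression.columns)
    else:
        X = np.asarray(expression, dtype=float)
        gene_ids = list(gene_ids)
        cell_ids = (list(cell_ids) if cell_ids is not None
                    else [f"c{i}" for i in range(X.shape[1])])
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    in_set = np.array([g in set(gene_set) for g in gene_ids])
    if not in_set.any():
        raise ValueError("gene set absent from the expression matrix")
    n_genes = len(gene_ids)
    window = math.ceil(top_fraction * n_genes)
    n_set = int(in_set.sum())
    # tie-break by ascending gene id: stable sort on (-expr) after pre-sorting
    # rows by gene id
    id_order = np.array(sorted(range(n_genes), key=lambda i: gene_ids[i]))
    Xo = X[id_order]
    so = in_set[id_order]
    # max possible area: all set genes occupy the top ranks
    max_curve = np.minimum(np.arange(1, window + 1), n_set)
    max_area = float(max_curve.sum())
    scores = np.empty(X.shape[1])
    order = np.argsort(-Xo, axis=0, kind="stable")
    hits = so[order]                        # window x cells after slicing
    cum = np.cumsum(hits[:window, :], axis=0)
    scores = cum.sum(axis=0) / max_area
    return pd.Series(scores, index=cell_ids, name="rank_auc")


def pseudobulk(cell_scores: pd.DataFrame, cell_metadata: pd.DataFrame):
    """Per-sample arithmetic mean of per-cell scores.

    ``cell_scores`` is cell x program; ``cell_metadata`` maps ``barcode`` to
    ``sample_id``. Returns (sample x program means, per-sample cell counts);
    samples with a single cell are flagged in the log.
    """
    meta = cell_metadata.set_index("barcode")
    unknown = [c for c in cell_scores.index if c not in meta.index]
    if unknown:
        raise ValueError(f"cells with unknown sample id: {unknown[:5]}"
                         f"{'...' if len(unknown) > 5 else ''}")
    sample_of = meta.loc[cell_scores.index, "sample_id"]
    means = cell_scores.groupby(sample_of.to_numpy()).mean()
    counts = sample_of.value_counts().sort_index()
    low = counts[counts == 1]
    if len(low):
        log.warning("samples with a single scored cell: %s", list(low.index))
    means.index.name = "sample_id"
    return means, counts


def transfer_validation(pseudobulk_scores: pd.DataFrame,
                        clinical: ClinicalTable) -> pd.DataFrame:
    """Case/control Welch t-tests and Spearman-vs-VAS for proxy scores.

    Both families are BH-adjusted across the tested programs. Cases are all
    non-HC samples.
    """
    groups = clinical.groups()
    vas = clinical.vas()
    case_ids = groups[groups != "HC"].index
    hc_ids = groups[groups == "HC"].index
    t_rows, s_rows = [], []
    for p in pseudobulk_scores.columns:
        x = pseudobulk_scores[p].dropna()
        a = x[x.index.intersection(case_ids)].to_numpy()
        b = x[x.index.intersection(hc_ids)].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"program {p}: both groups need >= 2 samples")
        t, pv = stats.ttest_ind(a, b, equal_var=False)
        t_rows.append((p, "welch_t", "case_vs_HC", float(t), float(pv),
                       "up" if t > 0 else "down"))
        common = x.index.intersection(vas.index)
        if len(common) < 5:
            raise ValueError(f"program {p}: fewer than 5 samples for "
                             f"Spearman")
        rho, ps = stats.spearmanr(x[common], vas[common])
        s_rows.append((p, "spearman_vas", "vas_global", float(rho),
                       float(ps), "up" if rho > 0 else "down"))
    cols = ["unit", "test", "comparison", "statistic", "p", "direction"]
    tt = pd.DataFrame(t_rows, columns=cols)
    tt["p_adj"] = multipletests(tt["p"], method="fdr_bh")[1]
    tt["family"] = "transfer_case_control"
    sp = pd.DataFrame(s_rows, columns=cols)
    sp["p_adj"] = multipletests(sp["p"], method="fdr_bh")[1]
    sp["family"] = "transfer_vas"
    return pd.concat([tt, sp], ignore_index=True)
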