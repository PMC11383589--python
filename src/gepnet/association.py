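"""Clinical-covariate statistics for programs, cell compositions and modules.

Covers the cohort-level tests used around the program network: cell-type
composition tests (Kruskal-Wallis with Dunn's post hoc, Holm-adjusted, plus
Spearman against the physician-global VAS, BH-adjusted), per-program
case/control Welch t-tests, four-group one-way ANOVA with Tukey HSD,
derivation of cross-cell-type gene modules by hierarchical clustering of
shared differentially expressed genes, binned-control per-cell module
scoring, and Spearman activity correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .containers import GROUP_ORDER, ClinicalTable

log = logging.getLogger(__name__)

#: group pairs reported by the composition analysis
COMPOSITION_PAIRS = (
    ("TreatmentNaive", "HC"),
    ("TreatmentNaive", "Inactive"),
    ("Inactive", "HC"),
)


def _bh(p):
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def _holm(p):
    return multipletests(np.asarray(p, dtype=float), method="holm")[1]


# --------------------------------------------------------------------------
# Dunn's post hoc z-test (rank-based, tie-corrected)


def dunn_posthoc(groups: dict, pairs) -> pd.DataFrame:
    """Two-tailed Dunn's z-tests on the pooled ranks of ``groups``.

    ``groups`` maps label -> 1-D array of values; ``pairs`` lists label
    pairs. Uses the standard tie-corrected variance
    N(N+1)/12 - sum(t^3 - t)/(12(N-1)). Raw p-values only; adjust outside.
    """
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float)
                             for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = len(values)
    ranks = stats.rankdata(values)
    offsets, start = {}, 0
    for g in labels:
        offsets[g] = ranks[start : start + sizes[g]]
        start += sizes[g]
    mean_rank = {g: offsets[g].mean() for g in labels}
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in pairs:
        se = np.sqrt(max(base_var, 0.0) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0.0:  # all observations tied
            rows.append((a, b, 0.0, 1.0))
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])


# --------------------------------------------------------------------------
# composition analysis


def composition_test(cell_counts: pd.DataFrame,
                     clinical: ClinicalTable) -> pd.DataFrame:
    """Cell-type composition versus disease group and disease activity.

    ``cell_counts`` is sample x cell type (cells per sample). Per cell type:
    Kruskal-Wallis on per-sample proportions across the three compared groups
    (treatment-naive, inactive, healthy controls), Dunn's post hoc z-tests
    for the three pairs with Holm adjustment within the cell type; and,
    separately, Spearman correlation of proportion against the VAS score
    with BH adjustment across cell types. Groups with fewer than 2 samples
    are skipped (logged).
    """
    props = cell_counts.div(cell_counts.sum(axis=1), axis=0)
    groups = clinical.groups()
    vas = clinical.vas()
    tested_groups = ("HC", "Inactive", "TreatmentNaive")
    rows = []
    spearman_rows = []
    for ct in props.columns:
        x = props[ct]
        by_group = {
            g: x[groups[groups == g].index.intersection(x.index)].to_numpy()
            for g in tested_groups
        }
        usable = {g: v for g, v in by_group.items() if len(v) >= 2}
        skipped = sorted(set(tested_groups) - set(usable))
        if skipped:
            log.warning("cell type %s: groups with < 2 samples skipped: %s",
                        ct, skipped)
        pooled = np.concatenate(list(usable.values())) if usable else []
        if len(usable) >= 2 and len(np.unique(pooled)) > 1:
            H, p_kw = stats.kruskal(*usable.values())
            rows.append((ct, "kruskal_wallis", "all", float(H), float(p_kw),
                         np.nan, ""))
            pairs = [(a, b) for a, b in COMPOSITION_PAIRS
                     if a in usable and b in usable]
            if pairs:
                dunn = dunn_posthoc(usable, pairs)
                adj = _holm(dunn["p"])
                for (_, r), q in zip(dunn.iterrows(), adj):
                    rows.append((ct, "dunn", f"{r.group_a}_vs_{r.group_b}",
                                 r.z, r.p, float(q),
                                 "up" if r.z > 0 else "down"))
        common = x.index.intersection(vas.index)
        if len(common) >= 5 and x[common].nunique() > 1:
            rho, p_s = stats.spearmanr(x[common], vas[common])
            spearman_rows.append((ct, float(rho), float(p_s)))
    out = pd.DataFrame(
        rows, columns=["unit", "test", "comparison", "statistic", "p",
                       "p_adj", "direction"],
    )
    out["family"] = "composition_groups"
    if spearman_rows:
        sp = pd.DataFrame(spearman_rows, columns=["unit", "statistic", "p"])
        sp["p_adj"] = _bh(sp["p"])
        sp["test"] = "spearman_vas"
        sp["comparison"] = "vas_global"
        sp["direction"] = np.where(sp["statistic"] > 0, "up", "down")
        sp["family"] = "composition_vas"
        out = pd.concat([out, sp[out.columns]], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# program-level tests


def program_case_control(scores: pd.DataFrame,
                         clinical: ClinicalTable) -> pd.DataFrame:
    """Welch two-tailed t-test per program, cases (all non-HC) versus HC."""
    groups = clinical.groups()
    case_ids = groups[groups != "HC"].index
    hc_ids = groups[groups == "HC"].index
    rows = []
    for p in scores.columns:
        x = scores[p].dropna()
        a = x[x.index.intersection(case_ids)].to_numpy()
        b = x[x.index.intersection(hc_ids)].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"program {p}: both groups need >= 2 samples")
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            log.warning("program %s: zero variance and equal means", p)
            rows.append((p, 0.0, 1.0, "none", True))
            continue
        t, pv = stats.ttest_ind(a, b, equal_var=False)
        rows.append((p, float(t), float(pv),
                     "up" if t > 0 else "down", False))
    out = pd.DataFrame(rows, columns=["unit", "statistic", "p", "direction",
                                      "degenerate"])
    out["test"] = "welch_t"
    out["comparison"] = "case_vs_HC"
    out["p_adj"] = _bh(out["p"])
    out["family"] = "program_case_control"
    return out


def program_activity_anova(scores: pd.DataFrame,
                           clinical: ClinicalTable) -> pd.DataFrame:
    """Four-group one-way ANOVA per program with Tukey HSD post hoc.

    Groups are the ordered disease-activity strata; a missing group is an
    error naming it. Returns one ``anova`` row per program plus six
    ``tukey`` rows (all group pairs).
    """
    groups = clinical.groups()
    rows = []
    for p in scores.columns:
        x = scores[p].dropna()
        by_group = {}
        for g in GROUP_ORDER:
            ids = groups[groups == g].index.intersection(x.index)
            if len(ids) < 2:
                raise ValueError(
                    f"program {p}: group {g!r} has < 2 scored samples"
                )
            by_group[g] = x[ids].to_numpy()
        F, pv = stats.f_oneway(*[by_group[g] for g in GROUP_ORDER])
        rows.append((p, "anova", "all", float(F), float(pv), ""))
        tk = stats.tukey_hsd(*[by_group[g] for g in GROUP_ORDER])
        for i, ga in enumerate(GROUP_ORDER):
            for j in range(i + 1, len(GROUP_ORDER)):
                gb = GROUP_ORDER[j]
                diff = by_group[ga].mean() - by_group[gb].mean()
                rows.append((p, "tukey", f"{ga}_vs_{gb}",
                             float(tk.statistic[i, j]),
                             float(tk.pvalue[i, j]),
                             "up" if diff > 0 else "down"))
    out = pd.DataFrame(rows, columns=["unit", "test", "comparison",
                                      "statistic", "p", "direction"])
    out["p_adj"] = out["p"]  # ANOVA reported raw; Tukey is family-adjusted
    out["family"] = "program_activity"
    return out


# --------------------------------------------------------------------------
# gene modules and module scoring


def derive_gene_modules(de_tables: dict, avg_expression: pd.DataFrame,
                        n_modules: int = 7) -> list:
    """Cluster recurrently differential genes into cross-cell-type modules.

    ``de_tables`` maps cell type -> iterable of significant gene ids; only
    genes significant in at least 2 cell types are kept. Their
    (sample, cell type) average-expression profiles (``avg_expression``:
    gene x (sample, cell type) columns) are row-standardized and clustered
    by complete-linkage hierarchical clustering on Euclidean distance, cut
    into ``n_modules`` modules, returned largest first as (label, genes,
    source) dicts.
    """
    counts = {}
    for ct, genes in de_tables.items():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    keep = sorted(g for g, c in counts.items() if c >= 2)
    keep = [g for g in keep if g in avg_expression.index]
    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 genes are differential in >= 2 cell types"
        )
    M = avg_expression.loc[keep].to_numpy(dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=0, keepdims=True)
    M = (M - mu) / np.where(sd > 0, sd, 1.0)
    n_modules = min(n_modules, len(keep))
    Z = linkage(M, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_modules, criterion="maxclust")
    modules = {}
    for g, lab in zip(keep, labels):
        modules.setdefault(lab, []).append(g)
    ordered = sorted(modules.values(), key=lambda gs: (-len(gs), gs[0]))
    return [
        {"label": f"module_{i}", "genes": sorted(gs),
         "source": "hierarchical_complete_euclidean"}
        for i, gs in enumerate(ordered, start=1)
    ]


def module_score(expression: pd.DataFrame, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Binned-control per-cell score of a gene set.

    ``expression`` is a log-normalized gene x cell frame. Genes are binned
    into ``n_bins`` by mean expression; for each set gene, ``n_ctrl``
    control genes are sampled with replacement from its bin, and the score
    is mean(set-gene expression) - mean(control expression) per cell.
    """
    genes = list(expression.index)
    gset = [g for g in gene_set if g in expression.index]
    missing = sorted(set(gene_set) - set(gset))
    if not gset:
        raise ValueError(f"no gene of the set is in the matrix; "
                         f"missing: {missing[:10]}")
    if missing:
        log.warning("module score: %d set genes absent (e.g. %s)",
                    len(missing), missing[:5])
    rng = np.random.default_rng(seed)
    X = expression.to_numpy(dtype=float)
    mean_expr = X.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    # equal-occupancy bins on the mean-expression ranking
    splits = np.array_split(order, min(n_bins, len(genes)))
    for b, idx in enumerate(splits):
        bin_of[idx] = b
    gene_idx = {g: i for i, g in enumerate(genes)}
    ctrl_rows = []
    for g in gset:
        b = bin_of[gene_idx[g]]
        pool = np.where(bin_of == b)[0]
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    set_idx = np.array([gene_idx[g] for g in gset])
    score = X[set_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=expression.columns, name="module_score")


def log_normalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """log1p of per-cell counts scaled to ``target_sum`` (additive scale for
    module scoring)."""
    tot = counts.sum(axis=0)
    scaled = counts.div(tot.where(tot > 0, 1.0), axis=1) * target_sum
    return np.log1p(scaled)


def collapse_donors(sample_scores: pd.DataFrame, clinical: ClinicalTable):
    """Average per-sample scores within donor for sensitivity analyses.

    Group tests in the pipeline treat longitudinal samples from one donor as
    independent, replicating the analysed study's convention; this helper
    produces donor-level scores (mean over the donor's samples) and a
    donor-level clinical table (first sample's covariates) for checking how
    much that convention matters. No claim is made about which analysis is
    correct.
    """
    donors = clinical.table.set_index("sample_id")["donor_id"]
    common = sample_scores.index.intersection(donors.index)
    collapsed = sample_scores.loc[common].groupby(
        donors[common].to_numpy()
    ).mean()
    collapsed.index.name = "sample_id"  # donor id stands in for sample id
    first = clinical.table.drop_duplicates("donor_id", keep="first").copy()
    first["sample_id"] = first["donor_id"]
    return collapsed, ClinicalTable(first.reset_index(drop=True))


def score_activity_correlation(sample_scores: pd.DataFrame,
                               clinical: ClinicalTable,
                               family: str = "activity") -> pd.DataFrame:
    """Spearman correlation of per-sample scores against the VAS, BH within
    the family of scored units. Constant score columns are flagged."""
    vas = clinical.vas()
    rows = []
    for unit in sample_scores.columns:
        x = sample_scores[unit].dropna()
        common = x.index.intersection(vas.index)
        if len(common) < 5:
            raise ValueError(f"unit {unit}: fewer than 5 samples with both "
                             f"score and VAS")
        if x[common].nunique() == 1:
            log.warning("unit %s: constant scores; rho undefined", unit)
            rows.append((unit, np.nan, np.nan, True))
            continue
        rho, p = stats.spearmanr(x[common], vas[common])
        rows.append((unit, float(rho), float(p), False))
    out = pd.DataFrame(rows, columns=["unit", "statistic", "p", "degenerate"])
    ok = ~out["p"].isna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = _bh(out.loc[ok, "p"])
    out["test"] = "spearman_vas"
    out["comparison"] = "vas_global"
    out["direction"] = np.where(out["statistic"] > 0, "up", "down")
    out["family"] = family
    return out
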