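"""Gene-set machinery: GMT parsing, preranked GSEA, batch FDR, ORA.

The preranked enrichment score is the classic maximum deviation of a running
sum that increments at set genes (proportionally to |score|^w) and decrements
uniformly at misses. Significance comes from gene-label permutations with a
plus-one correction, so p-values are never zero; NES normalizes the observed
ES by the mean magnitude of same-sign null scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict                     # name -> list of gene ids (normalized)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, min_size: int = 1, max_size: int = 10**9):
        kept = {n: g for n, g in self.sets.items()
                if min_size <= len(g) <= max_size}
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )


def _normalize_gene(g: str) -> str:
    return g.strip().upper()


def read_gmt(path, min_size_warn: int = 5) -> GeneSetCollection:
    """Parse a standard GMT file (name, description, tab-separated genes).

    Gene ids are uppercased; a case-insensitive collision within one set is
    an error, as are duplicate set names and lines with fewer than 3 fields.
    """
    sets, desc = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: malformed GMT line (need name, "
                    f"description and >= 1 gene)"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            genes = [_normalize_gene(g) for g in fields[2:] if g.strip()]
            if len(set(genes)) != len(genes):
                raise ValueError(
                    f"{path}:{ln}: set {name!r} has case-insensitive "
                    f"duplicate gene ids"
                )
            if not genes:
                raise ValueError(f"{path}:{ln}: set {name!r} has no genes")
            if len(genes) < min_size_warn:
                log.warning("gene set %r has only %d genes", name, len(genes))
            sets[name] = genes
            desc[name] = fields[1]
    return GeneSetCollection(sets, desc)


def enrichment_score(scores: np.ndarray, in_set: np.ndarray,
                     weight_exponent: float = 1.0) -> float:
    """ES of a pre-ordered ranking: max-deviation running sum.

    ``scores`` are the ranking scores in list order (descending), ``in_set``
    a boolean hit mask. Hits increment by |score|^w normalized over hits,
    misses decrement uniformly. Degenerate cases (all genes in the set, or
    no hits) return 0.
    """
    n = len(scores)
    n_hit = int(in_set.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(in_set, w, 0.0)
    tot = hit_w.sum()
    if tot <= 0:  # all hit scores are zero: fall back to uniform increments
        hit_w = in_set.astype(float)
        tot = hit_w.sum()
    steps = hit_w / tot - (~in_set) / float(n_miss)
    running = np.cumsum(steps)
    mx, mn = float(running.max()), float(running.min())
    # deviation of larger magnitude wins; exact ties resolve positive
    return mx if mx >= -mn - 1e-12 else mn


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list
    flagged: bool = False


def preranked_gsea(ranking: pd.Series, gene_set, n_perm: int = 999,
                   weight_exponent: float = 1.0, seed: int = 0,
                   set_name: str = "") -> GSEAResult:
    """Preranked GSEA for one gene set.

    ``ranking`` maps gene id -> real score, ordered descending with ties
    already broken (strictly ordered index). The permutation null shuffles
    gene labels; p is computed among same-sign null scores with a plus-one
    correction, and NES = ES / mean(|null ES| of the same sign).
    """
    genes = list(ranking.index)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking has duplicate gene ids")
    scores = ranking.to_numpy(dtype=float)
    gene_set = {_normalize_gene(g) for g in gene_set}
    in_set = np.array([g.upper() in gene_set for g in genes])
    if not in_set.any():
        log.warning("gene set %r does not intersect the ranking", set_name)
        return GSEAResult(set_name, 0.0, 0.0, 1.0, 1.0, [], flagged=True)
    if in_set.all():
        log.warning("gene set %r covers the whole ranking; ES degenerate",
                    set_name)
        return GSEAResult(set_name, 0.0, 0.0, 1.0, 1.0, [], flagged=True)
    es = enrichment_score(scores, in_set, weight_exponent)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = in_set.copy()
    for b in range(n_perm):
        rng.shuffle(mask)
        null[b] = enrichment_score(scores, mask, weight_exponent)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if es == 0:
        p, nes = 1.0, 0.0
    else:
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (len(same) + 1.0)
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and denom > 0 else 0.0
    # leading edge: hits at or before the running-sum extremum
    w = np.abs(scores) ** weight_exponent
    hit_w = np.where(in_set, w, 0.0)
    tot = hit_w.sum()
    if tot <= 0:
        hit_w, tot = in_set.astype(float), float(in_set.sum())
    steps = hit_w / tot - (~in_set) / float((~in_set).sum())
    running = np.cumsum(steps)
    if es >= 0:
        peak = int(np.argmax(running))
        leading = [g for g, h in zip(genes[: peak + 1], in_set[: peak + 1]) if h]
    else:
        peak = int(np.argmin(running))
        leading = [g for g, h in zip(genes[peak:], in_set[peak:]) if h]
    return GSEAResult(set_name, es, float(nes), float(p), float(p), leading)


def batch_gsea(marker_tables: dict, collection: GeneSetCollection,
               n_perm: int = 999, fdr_cutoff: float = 0.01,
               seed: int = 0, weight_exponent: float = 1.0) -> pd.DataFrame:
    """Run preranked GSEA for every (program, gene set) combination.

    ``marker_tables`` maps program id -> marker table (long frame with
    ``gene``, ``marker_score``, ``rank`` columns as produced by
    ``marker_scores``). Rankings are ordered by rank (ascending = best
    first). BH correction is applied across gene sets within each program;
    rows are flagged significant at FDR < ``fdr_cutoff``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for prog in sorted(marker_tables):
        tab = marker_tables[prog]
        tab = tab.sort_values("rank")
        ranking = pd.Series(tab["marker_score"].to_numpy(),
                            index=tab["gene"].to_numpy())
        pvals, results = [], []
        for name in collection.sets:
            res = preranked_gsea(
                ranking, collection.sets[name], n_perm=n_perm,
                weight_exponent=weight_exponent,
                seed=int(rng.integers(2**31)), set_name=name,
            )
            results.append(res)
            pvals.append(res.p)
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for res, q in zip(results, fdrs):
            rows.append((prog, res.set_name, res.es, res.nes, res.p,
                         float(q), q < fdr_cutoff,
                         ";".join(res.leading_edge), res.flagged))
    return pd.DataFrame(
        rows, columns=["program", "gene_set", "es", "nes", "p", "fdr",
                       "significant", "leading_edge", "flagged"],
    )


def ora_hypergeometric(hit_genes, gene_set, universe):
    """Upper-tail hypergeometric overrepresentation test.

    Returns (p, fold_enrichment) where fold = (overlap/|hits|) /
    (|set|/|universe|).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(hit_genes)
    if not hits:
        raise ValueError("empty hit list")
    gset = set(gene_set)
    if not hits <= universe or not gset <= universe:
        raise ValueError("hits and gene set must be subsets of the universe")
    N, K, n = len(universe), len(gset), len(hits)
    k = len(hits & gset)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K else np.nan
    return p, float(fold)
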