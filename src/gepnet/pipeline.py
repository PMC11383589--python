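"""End-to-end pipeline driver: factorize -> filter -> network -> enrich ->
associate (-> transfer), with a manifest for bitwise reproducibility.

A single global seed is expanded into per-stage sub-seeds by a fixed counter
scheme (SeedSequence spawn order is documented in the manifest), so stages
can be rerun individually and full reruns with the same config and seed
reproduce every output table byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import factorize as fz
from . import network as nw
from .association import program_activity_anova, program_case_control, \
    score_activity_correlation, composition_test
from .io import file_checksum, read_counts, read_gene_sets_or_none, write_table
from .transfer import pseudobulk, rank_auc_score, top_markers, \
    transfer_validation

log = logging.getLogger(__name__)

#: fixed spawn order of per-stage sub-seeds
STAGES = ("factorize", "network", "enrich", "associate", "transfer")


@dataclass
class PipelineConfig:
    counts_dir: str
    out_dir: str
    gene_sets: str = None
    validation_counts_dir: str = None
    n_top_genes: int = 2000
    k_grid: list = field(default_factory=lambda: list(range(5, 21)))
    restarts: int = 5
    min_cells: int = 10
    max_sample_share: float = 0.5
    min_active_samples: int = 3
    n_boot: int = 1000
    n_perm: int = 999
    alpha: float = 0.05
    fdr: float = 0.01
    top_fraction: float = 0.05
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0

    def validate(self):
        if not os.path.isdir(self.counts_dir):
            raise FileNotFoundError(f"counts dir not found: {self.counts_dir}")
        if self.gene_sets is not None and not os.path.exists(self.gene_sets):
            raise FileNotFoundError(
                f"gene set file not found: {self.gene_sets}"
            )
        if (self.validation_counts_dir is not None
                and not os.path.isdir(self.validation_counts_dir)):
            raise FileNotFoundError(
                f"validation counts dir not found: "
                f"{self.validation_counts_dir}"
            )
        if sorted(self.k_grid) != list(self.k_grid):
            raise ValueError("k_grid must be sorted ascending")


def stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31))
            for stage, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages; returns the report directory.

    Fails fast on invalid configuration; on a stage failure the partial
    outputs written so far are kept and the error names the stage.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "inputs": {},
        "tables": [],
    }
    stage = "read"
    try:
        counts, metadata, clinical, adt = read_counts(config.counts_dir)
        collection = read_gene_sets_or_none(config.gene_sets)

        # ---- factorize ---------------------------------------------------
        stage = "factorize"
        all_scores = []
        markers = {}
        models = {}
        retained_all = []
        for i, (ct, cm) in enumerate(sorted(counts.items())):
            sub_seed = seeds["factorize"] + 101 * i
            X, genes = fz.prepare_matrix(
                cm, min(config.n_top_genes, cm.n_genes)
            )
            grid = [k for k in config.k_grid if k <= min(X.shape)]
            sel = fz.weighted_subtrees_rank_selection(
                X, grid, n_restarts=config.restarts, seed=sub_seed,
                max_iter=config.max_iter, tol=config.tol,
            )
            model = fz.consensus_model(
                X, sel.chosen_k, n_restarts=config.restarts, seed=sub_seed,
                max_iter=config.max_iter, tol=config.tol, gene_ids=genes,
                cell_ids=cm.cell_ids, cell_type=ct,
            )
            models[ct] = model
            elbow = pd.DataFrame(
                {"k": sel.k_grid,
                 "metric": [sel.metric[k] for k in sel.k_grid]}
            )
            elbow["chosen"] = elbow["k"] == sel.chosen_k
            _emit(elbow, out, f"rank_selection_{ct}.tsv", manifest)
            _emit(model.W.reset_index().rename(columns={"index": "gene"}),
                  out, f"loadings_{ct}.tsv", manifest)
            mk = fz.marker_scores(model)
            for p, tab in mk.groupby("program"):
                markers[p] = tab.reset_index(drop=True)
            _emit(mk, out, f"markers_{ct}.tsv", manifest)
            scores = fz.sample_program_scores(model, metadata,
                                              min_cells=config.min_cells)
            retained, report = fz.filter_outlier_programs(
                scores, max_sample_share=config.max_sample_share,
                min_active_samples=config.min_active_samples,
            )
            _emit(report, out, f"outlier_filter_{ct}.tsv", manifest)
            retained_all += retained
            all_scores.append(scores[retained])
        scores = pd.concat(all_scores, axis=1)
        _emit(scores.reset_index(), out, "sample_scores.tsv", manifest)

        # ---- network -----------------------------------------------------
        stage = "network"
        edge_stats = nw.correlate_programs(scores, n_boot=config.n_boot,
                                           seed=seeds["network"])
        net = nw.build_network(edge_stats, alpha=config.alpha,
                               layout_seed=seeds["network"])
        nw.detect_modules(net, seed=seeds["network"])
        _emit(net.edge_table(), out, "network_edges.tsv", manifest)
        _emit(net.module_table(), out, "network_modules.tsv", manifest)

        # ---- enrichment ----------------------------------------------------
        stage = "enrich"
        if collection is not None:
            from .enrichment import batch_gsea

            gsea = batch_gsea(
                {p: markers[p] for p in retained_all if p in markers},
                collection, n_perm=config.n_perm, fdr_cutoff=config.fdr,
                seed=seeds["enrich"],
            )
            _emit(gsea, out, "gsea.tsv", manifest)
            mod_enrich = nw.module_enrichment_pvalues(
                net, gsea, n_perm=config.n_perm, seed=seeds["enrich"],
            )
            _emit(mod_enrich, out, "module_enrichment.tsv", manifest)

        # ---- association ---------------------------------------------------
        stage = "associate"
        comp = metadata.groupby(["sample_id", "cell_type"]).size() \
            .unstack(fill_value=0)
        _emit(composition_test(comp, clinical), out,
              "composition_tests.tsv", manifest)
        _emit(program_case_control(scores, clinical), out,
              "case_control.tsv", manifest)
        _emit(program_activity_anova(scores, clinical), out,
              "activity_anova.tsv", manifest)
        _emit(score_activity_correlation(scores, clinical,
                                         family="program_vas"),
              out, "activity_correlation.tsv", manifest)

        # ---- transfer (optional) -------------------------------------------
        if config.validation_counts_dir:
            stage = "transfer"
            vcounts, vmeta, vclinical, _ = read_counts(
                config.validation_counts_dir
            )
            cell_tabs = {}
            for ct, cm in sorted(vcounts.items()):
                if ct not in models:
                    continue
                per_prog = {}
                for p in models[ct].program_ids:
                    gene_list = top_markers(markers[p],
                                            fraction=config.top_fraction)
                    per_prog[p] = rank_auc_score(
                        cm, gene_list, top_fraction=config.top_fraction
                    )
                cell_tabs[ct] = pd.DataFrame(per_prog)
            proxy_cells = pd.concat(cell_tabs.values())
            pb, n_cells = pseudobulk(proxy_cells, vmeta)
            _emit(pb.reset_index(), out, "proxy_pseudobulk.tsv", manifest)
            _emit(transfer_validation(pb, vclinical), out,
                  "transfer_validation.tsv", manifest)

        stage = "manifest"
        for name in ("metadata.csv", "clinical.csv"):
            p = os.path.join(config.counts_dir, name)
            if os.path.exists(p):
                manifest["inputs"][name] = file_checksum(p)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out


def _emit(df: pd.DataFrame, out: str, name: str, manifest: dict) -> None:
    path = os.path.join(out, name)
    write_table(df, path)
    manifest["tables"].append(name)
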