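"""Synthetic multi-sample single-cell cohorts with planted expression programs.

The generator emulates the structure of a case/control pediatric autoimmune
cohort profiled by CITEseq: ~27 PBMC samples in four disease-activity groups
(healthy controls, inactive, active, and treatment-naive disease), several
major immune cell types, and, within each cell type, a small number of planted
gene expression programs (GEPs). Per-sample program intensities covary across
cell types in planted modules; one designated "IFN-like" module is shifted
with disease group and drives both a 0-10 physician-global VAS activity score
and a correlated surface-protein (ADT) biomarker channel.

Counts are drawn gene-wise from a negative binomial around ``libsize * W @ h``
(Poisson in the zero-dispersion limit); every random draw is controlled by a
single integer seed, so identical configs reproduce byte-identical cohorts.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import GROUP_ORDER, ClinicalTable, CountMatrix, program_label

DEFAULT_CELL_TYPES = ("B", "CD4T", "CD8T", "NK", "gdT", "Myeloid")


@dataclass
class ModuleSpec:
    """One planted cross-cell-type module.

    members are (cell_type, program) pairs with 1-based program indices;
    rho is the latent intra-module correlation in [0, 1).
    """

    module_id: int
    members: list
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"module {self.module_id}: rho must be in [0, 1)")
        if len(self.members) < 2:
            raise ValueError(f"module {self.module_id}: needs >= 2 members")


def default_module_spec(cell_types=DEFAULT_CELL_TYPES, programs_per_type: int = 5):
    """Three planted modules mirroring the analysed cohort's structure.

    Module 1 (the designated activity module) has one program per cell type,
    like a pan-cell-type interferon response; modules 2 and 3 span subsets of
    cell types. Remaining programs are left uncorrelated.
    """
    cts = list(cell_types)
    spec = []
    if len(cts) >= 2:
        spec.append(ModuleSpec(1, [(ct, 1) for ct in cts], rho=0.7))
    elif programs_per_type >= 2:
        # single-cell-type design: an intra-type activity module
        spec.append(ModuleSpec(1, [(cts[0], 1), (cts[0], 2)], rho=0.7))
    if programs_per_type >= 2 and len(cts) >= 4:
        spec.append(ModuleSpec(2, [(ct, 2) for ct in cts[:4]], rho=0.6))
    if programs_per_type >= 3 and len(cts) >= 3:
        spec.append(ModuleSpec(3, [(ct, 3) for ct in cts[-3:]], rho=0.6))
    return spec


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator; defaults mirror the study cohort shape:
    27 samples split 5/6/7/9 over HC < Inactive < Active < TreatmentNaive."""

    n_samples: int = 27
    group_sizes: dict = field(
        default_factory=lambda: {
            "HC": 5, "Inactive": 6, "Active": 7, "TreatmentNaive": 9,
        }
    )
    n_cell_types: int = 6
    genes_per_type: int = 1000
    programs_per_type: int = 5
    cells_per_sample_per_type: int = 100
    loading_sparsity: float = 0.9
    module_spec: list = None
    activity_module: int = 1
    activity_effect: float = 2.0  # latent-sd shift per ordered group step
    libsize_mean: int = 2000
    overdispersion: float = 0.3
    usage_concentration: float = 10.0  # Dirichlet concentration around sample intensity
    latent_loc: float = 1.5  # shift before softplus; keeps the map near-linear
    vas_noise: float = 0.5  # within-group spread of the activity latent
    seed: int = 0
    loading_seed: int = None  # fix planted loadings across cohort seeds
    # (independent validation cohorts share programs with a training cohort)

    def __post_init__(self):
        if sum(self.group_sizes.values()) != self.n_samples:
            raise ValueError("group sizes must sum to n_samples")
        if set(self.group_sizes) != set(GROUP_ORDER):
            raise ValueError(f"group_sizes must cover exactly {GROUP_ORDER}")
        for name in ("n_samples", "n_cell_types", "genes_per_type",
                     "programs_per_type", "cells_per_sample_per_type",
                     "libsize_mean"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.loading_sparsity < 1.0:
            raise ValueError("loading_sparsity must be in [0, 1)")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")
        self.cell_types = list(DEFAULT_CELL_TYPES[: self.n_cell_types])
        if self.n_cell_types > len(DEFAULT_CELL_TYPES):
            self.cell_types += [
                f"CT{i}" for i in range(len(DEFAULT_CELL_TYPES), self.n_cell_types)
            ]
        if self.module_spec is None:
            self.module_spec = default_module_spec(
                self.cell_types, self.programs_per_type
            )
        seen = {}
        for m in self.module_spec:
            for ct, p in m.members:
                if ct not in self.cell_types:
                    raise ValueError(f"module {m.module_id}: unknown cell type {ct}")
                if not 1 <= p <= self.programs_per_type:
                    raise ValueError(f"module {m.module_id}: program index {p} out of range")
                key = (ct, p)
                if key in seen:
                    raise ValueError(f"program {key} assigned to two modules")
                seen[key] = m.module_id


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery testing."""

    true_loadings: dict          # cell type -> DataFrame gene x program, cols sum to 1
    true_sample_usage: pd.DataFrame  # sample x program-label latent intensity
    true_modules: dict           # program label -> module id
    true_activity_score: pd.Series   # per-sample VAS on the 0-10 scale
    activity_module: int = 1

    def activity_programs(self) -> list:
        return [p for p, m in self.true_modules.items() if m == self.activity_module]


@dataclass
class CohortDataset:
    counts: dict                 # cell type -> CountMatrix
    cell_metadata: pd.DataFrame  # barcode, sample_id, donor_id, cell_type, group, ...
    clinical: ClinicalTable
    adt: pd.DataFrame            # barcode x channel
    truth: GroundTruth


def plant_loadings(n_genes: int, k: int, sparsity: float, seed: int) -> np.ndarray:
    """Draw a gene x k nonnegative loading matrix with column sums of 1.

    Each program receives a disjoint set of "anchor" genes whose weights
    dominate the column (>= 3x the column mean wherever the gene budget
    allows at least 5 anchors), making the planted factorization identifiable.
    The remaining mass is spread over a random support whose size realizes the
    requested sparsity.
    """
    if k < 1 or n_genes < k:
        raise ValueError(f"need n_genes >= k >= 1, got n_genes={n_genes}, k={k}")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError(f"sparsity must be in [0, 1), got {sparsity}")
    rng = np.random.default_rng(seed)
    # anchors: disjoint across programs, and few enough that each can carry
    # >= 3x the column mean weight (needs n_genes > 3 * n_anchor)
    n_anchor = min(5, n_genes // k, max(1, (n_genes - 1) // 4))
    perm = rng.permutation(n_genes)
    W = np.zeros((n_genes, k))
    target_nnz = max(n_anchor + 1, int(round((1.0 - sparsity) * n_genes)))
    for j in range(k):
        anchors = perm[j * n_anchor : (j + 1) * n_anchor]
        others = np.setdiff1d(np.arange(n_genes), anchors)
        n_bg = min(len(others), max(1, target_nnz - n_anchor))
        bg = rng.choice(others, size=n_bg, replace=False)
        w = np.zeros(n_genes)
        w[bg] = rng.uniform(0.2, 1.0, size=n_bg)
        # anchors dominate every background gene (and hence the column mean)
        w[anchors] = w[bg].max() * (4.0 + 2.0 * rng.random(n_anchor))
        W[:, j] = w / w.sum()
    return W


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _latent_correlation(labels: list, modules: list) -> np.ndarray:
    p = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    corr = np.eye(p)
    for m in modules:
        members = [idx[program_label(ct, j)] for ct, j in m.members]
        for a in members:
            for b in members:
                if a != b:
                    corr[a, b] = m.rho
    return corr


def _nb_counts(mu: np.ndarray, overdispersion: float, rng: np.random.Generator):
    """Negative binomial with mean mu and var mu + phi * mu^2 (gamma-Poisson);
    exact Poisson when phi == 0."""
    if overdispersion == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / overdispersion
    rate = rng.gamma(shape, overdispersion * mu)
    return rng.poisson(rate)


def simulate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate a full cohort: counts per cell type, metadata, clinical table,
    one ADT biomarker channel, and the planted ground truth."""
    cfg = config
    if cfg.cells_per_sample_per_type < 1:
        raise ValueError("every cell type needs at least one cell per sample")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(4 + cfg.n_cell_types)
    rng_latent = np.random.default_rng(seeds[0])
    rng_cells = np.random.default_rng(seeds[1])
    rng_adt = np.random.default_rng(seeds[2])
    if cfg.loading_seed is not None:
        load_ss = np.random.SeedSequence(cfg.loading_seed).spawn(
            cfg.n_cell_types
        )
    else:
        load_ss = seeds[4:]
    load_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in load_ss]

    cell_types = cfg.cell_types
    prog_labels = [
        program_label(ct, j + 1)
        for ct in cell_types
        for j in range(cfg.programs_per_type)
    ]
    n_prog = len(prog_labels)

    # --- sample frame ------------------------------------------------------
    groups = []
    for g in GROUP_ORDER:
        groups += [g] * cfg.group_sizes[g]
    sample_ids = [f"S{i+1:02d}" for i in range(cfg.n_samples)]
    donor_ids = [f"D{i+1:02d}" for i in range(cfg.n_samples)]
    step = np.array([GROUP_ORDER.index(g) for g in groups], dtype=float)

    # --- latent per-sample program intensities -----------------------------
    corr = _latent_correlation(prog_labels, cfg.module_spec)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_prog))
    Z = rng_latent.standard_normal((cfg.n_samples, n_prog)) @ chol.T
    true_modules = {
        program_label(ct, j): m.module_id
        for m in cfg.module_spec
        for ct, j in m.members
    }
    act_cols = [
        i for i, lab in enumerate(prog_labels)
        if true_modules.get(lab) == cfg.activity_module
    ]
    for i in act_cols:
        Z[:, i] = Z[:, i] + cfg.activity_effect * step
    intensity = _softplus(Z + cfg.latent_loc)
    true_usage = pd.DataFrame(intensity, index=sample_ids, columns=prog_labels)

    # --- disease activity score (VAS) --------------------------------------
    # latent activity = ordered group step + noise, rank-mapped onto [0, 10];
    # independent of the module latent so that activity_effect alone controls
    # the module-activity association
    latent_act = step + cfg.vas_noise * rng_latent.standard_normal(
        cfg.n_samples
    )
    ranks = pd.Series(latent_act).rank(method="first").to_numpy()
    vas = np.round(10.0 * (ranks - 0.5) / cfg.n_samples, 1)
    vas_series = pd.Series(vas, index=sample_ids, name="vas_global")

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "donor_id": donor_ids,
                "group": groups,
                "vas_global": vas,
                "on_medication": [g == "Active" for g in groups],
            }
        )
    )

    # --- planted loadings ---------------------------------------------------
    gene_ids = [f"G{i:05d}" for i in range(cfg.genes_per_type)]
    true_loadings = {}
    for ct, sd in zip(cell_types, load_seeds):
        W = plant_loadings(cfg.genes_per_type, cfg.programs_per_type,
                           cfg.loading_sparsity, sd)
        true_loadings[ct] = pd.DataFrame(
            W, index=gene_ids,
            columns=[program_label(ct, j + 1) for j in range(cfg.programs_per_type)],
        )

    # --- cells: usages and counts ------------------------------------------
    counts = {}
    meta_rows = []
    n_cells_ct = cfg.n_samples * cfg.cells_per_sample_per_type
    for ct in cell_types:
        W = true_loadings[ct].to_numpy()
        cols = [prog_labels.index(program_label(ct, j + 1))
                for j in range(cfg.programs_per_type)]
        usage_cells = np.empty((n_cells_ct, cfg.programs_per_type))
        barcodes = []
        c0 = 0
        for s_idx, sid in enumerate(sample_ids):
            inten = intensity[s_idx, cols]
            alpha = cfg.usage_concentration * inten / inten.sum()
            n = cfg.cells_per_sample_per_type
            usage_cells[c0 : c0 + n] = rng_cells.dirichlet(alpha, size=n)
            for c in range(n):
                barcodes.append(f"{ct}-{sid}-C{c:04d}")
                meta_rows.append(
                    (barcodes[-1], sid, donor_ids[s_idx], ct, groups[s_idx],
                     vas[s_idx], groups[s_idx] == "Active")
                )
            c0 += n
        libsize = rng_cells.gamma(10.0, cfg.libsize_mean / 10.0, size=n_cells_ct)
        mu = (W @ usage_cells.T) * libsize[None, :]
        X = _nb_counts(mu, cfg.overdispersion, rng_cells)
        counts[ct] = CountMatrix(
            sp.csr_matrix(X.astype(np.int64)), gene_ids, barcodes, cell_type=ct
        )

    cell_metadata = pd.DataFrame(
        meta_rows,
        columns=["barcode", "sample_id", "donor_id", "cell_type", "group",
                 "vas_global", "on_medication"],
    )

    # --- ADT biomarker channel ----------------------------------------------
    # one surface-protein channel affine in the activity-module intensity
    if act_cols:
        mod_int = intensity[:, act_cols].mean(axis=1)
    else:
        mod_int = np.zeros(cfg.n_samples)
    sid_to_int = dict(zip(sample_ids, mod_int))
    per_cell = cell_metadata["sample_id"].map(sid_to_int).to_numpy()
    adt_val = 50.0 + 20.0 * per_cell + rng_adt.normal(0.0, 5.0, size=len(per_cell))
    adt = pd.DataFrame(
        {"barcode": cell_metadata["barcode"], "ADT_SIGLEC1": adt_val}
    ).set_index("barcode")

    truth = GroundTruth(
        true_loadings=true_loadings,
        true_sample_usage=true_usage,
        true_modules=true_modules,
        true_activity_score=vas_series,
        activity_module=cfg.activity_module,
    )
    return CohortDataset(counts, cell_metadata, clinical, adt, truth)


# --------------------------------------------------------------------------
# fixture IO


def write_fixture(dataset: CohortDataset, directory: str) -> None:
    """Write a cohort to disk as MTX + TSV/CSV + ground-truth JSON.

    Layout: one subdirectory per cell type holding ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv`` (genes as MTX rows), plus cohort-level
    ``metadata.csv``, ``clinical.csv``, ``adt.csv`` and ``truth.json``.
    """
    os.makedirs(directory, exist_ok=True)
    for ct, cm in dataset.counts.items():
        sub = os.path.join(directory, ct)
        os.makedirs(sub, exist_ok=True)
        mmwrite(os.path.join(sub, "matrix.mtx"), cm.values, field="integer")
        with open(os.path.join(sub, "features.tsv"), "w") as fh:
            for g in cm.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(os.path.join(sub, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
    dataset.cell_metadata.to_csv(os.path.join(directory, "metadata.csv"), index=False)
    dataset.clinical.table.to_csv(os.path.join(directory, "clinical.csv"), index=False)
    dataset.adt.to_csv(os.path.join(directory, "adt.csv"))
    truth = dataset.truth
    payload = {
        "activity_module": truth.activity_module,
        "true_modules": truth.true_modules,
        "true_activity_score": truth.true_activity_score.to_dict(),
        "true_sample_usage": {
            "index": list(truth.true_sample_usage.index),
            "columns": list(truth.true_sample_usage.columns),
            "values": truth.true_sample_usage.to_numpy().tolist(),
        },
        "true_loadings": {
            ct: {
                "index": list(df.index),
                "columns": list(df.columns),
                "values": df.to_numpy().tolist(),
            }
            for ct, df in truth.true_loadings.items()
        },
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(payload, fh)


def read_truth(directory: str) -> GroundTruth:
    """Reload the ground-truth record written by :func:`write_fixture`."""
    with open(os.path.join(directory, "truth.json")) as fh:
        payload = json.load(fh)
    usage = pd.DataFrame(
        payload["true_sample_usage"]["values"],
        index=payload["true_sample_usage"]["index"],
        columns=payload["true_sample_usage"]["columns"],
    )
    loadings = {
        ct: pd.DataFrame(d["values"], index=d["index"], columns=d["columns"])
        for ct, d in payload["true_loadings"].items()
    }
    return GroundTruth(
        true_loadings=loadings,
        true_sample_usage=usage,
        true_modules=payload["true_modules"],
        true_activity_score=pd.Series(payload["true_activity_score"],
                                      name="vas_global"),
        activity_module=payload["activity_module"],
    )
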