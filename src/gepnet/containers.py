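"""Shared data containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Ordered disease groups, least to most active/untreated.
GROUP_ORDER = ("HC", "Inactive", "Active", "TreatmentNaive")


@dataclass
class CountMatrix:
    """Sparse gene x cell raw count matrix for one cell type.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Nonnegative integer counts, genes in rows, cells in columns.
    gene_ids : list of str
        Row identifiers, unique.
    cell_ids : list of str
        Column identifiers (cell barcodes), unique.
    cell_type : str
        Label of the cell population the matrix was subset to.
    """

    values: sp.csr_matrix
    gene_ids: list
    cell_ids: list
    cell_type: str = ""

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    One row per sample: donor id, disease group (one of ``GROUP_ORDER``),
    physician-global VAS disease activity on a 0-10 scale, medication flag.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "donor_id", "group", "vas_global", "on_medication")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        bad = set(self.table["group"]) - set(GROUP_ORDER)
        if bad:
            raise ValueError(f"unknown disease groups: {sorted(bad)}")
        vas = self.table["vas_global"].to_numpy(dtype=float)
        if np.any((vas < 0) | (vas > 10)):
            raise ValueError("vas_global outside [0, 10]")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def groups(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def vas(self) -> pd.Series:
        return self.table.set_index("sample_id")["vas_global"].astype(float)


def program_label(cell_type: str, program: int) -> str:
    """Canonical node label for program ``program`` (1-based) of a cell type."""
    return f"{cell_type}_p{program}"
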