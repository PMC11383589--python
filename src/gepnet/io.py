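"""Readers and writers for the on-disk cohort layout.

Counts live in one directory per cell type as Matrix Market MTX (genes as
rows, cells as columns) with ``features.tsv`` and ``barcodes.tsv``; cohort
level files are ``metadata.csv``, ``clinical.csv`` and optionally
``adt.csv``. Plain and gzip-compressed MTX are both accepted. Orientation is
validated against the sidecar files and never silently transposed.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .containers import ClinicalTable, CountMatrix

log = logging.getLogger(__name__)


def _open_maybe_gzip(path):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find(directory, stem):
    for name in (stem, stem + ".gz"):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def read_count_dir(directory: str, cell_type: str = "") -> CountMatrix:
    """Read one cell type's MTX + features + barcodes triple."""
    mtx_path = _find(directory, "matrix.mtx")
    with _open_maybe_gzip(mtx_path) as fh:
        M = mmread(fh)
    M = sp.csr_matrix(M)
    with _open_maybe_gzip(_find(directory, "features.tsv")) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh
                 if line.strip()]
    with _open_maybe_gzip(_find(directory, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if M.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"{directory}: MTX is {M.shape[0]} x {M.shape[1]} but sidecars "
            f"give {len(genes)} genes x {len(barcodes)} barcodes "
            f"(transposed input is rejected, not fixed silently)"
        )
    if M.nnz and not np.allclose(M.data, np.round(M.data)):
        raise ValueError(f"{directory}: non-integer values in count matrix")
    M = sp.csr_matrix((M.data.astype(np.int64), M.indices, M.indptr),
                      shape=M.shape)
    return CountMatrix(M, genes, barcodes,
                       cell_type=cell_type or os.path.basename(directory))


def read_counts(directory: str):
    """Read a full fixture directory: per-cell-type counts plus metadata.

    Returns ``(counts, cell_metadata, clinical, adt_or_None)`` where
    ``counts`` maps cell type -> :class:`CountMatrix`. Every barcode in
    every count matrix must appear in the metadata.
    """
    meta_path = os.path.join(directory, "metadata.csv")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"missing metadata.csv in {directory}")
    metadata = pd.read_csv(meta_path)
    clinical = ClinicalTable(pd.read_csv(os.path.join(directory,
                                                      "clinical.csv")))
    known = set(metadata["barcode"])
    counts = {}
    for entry in sorted(os.listdir(directory)):
        sub = os.path.join(directory, entry)
        if not os.path.isdir(sub):
            continue
        try:
            _find(sub, "matrix.mtx")
        except FileNotFoundError:
            continue
        cm = read_count_dir(sub, cell_type=entry)
        missing = [b for b in cm.cell_ids if b not in known]
        if missing:
            raise ValueError(
                f"{entry}: barcode {missing[0]!r} not in metadata "
                f"({len(missing)} missing in total)"
            )
        counts[entry] = cm
    if not counts:
        raise FileNotFoundError(f"no count matrices under {directory}")
    adt = None
    adt_path = os.path.join(directory, "adt.csv")
    if os.path.exists(adt_path):
        adt = pd.read_csv(adt_path, index_col=0)
    return counts, metadata, clinical, adt


def read_gene_sets_or_none(path):
    from .enrichment import read_gmt

    if path is None:
        return None
    if not os.path.exists(path):
        raise FileNotFoundError(f"gene set file not found: {path}")
    return read_gmt(path)


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """TSV with stable column order and 12-significant-digit floats."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def file_checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
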