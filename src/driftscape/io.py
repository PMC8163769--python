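"""Readers and writers for the standard on-disk formats.

Expression comes in either as a delimited cells x genes table (header row =
gene names, first column = cell ids) or as a MatrixMarket sparse triplet
with sidecar gene/barcode name files. Per-cell metadata is a delimited
table keyed by cell_id. Gene sets are plain text, one symbol per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .preprocessing import ExpressionMatrix


def read_expression_table(path, meta_path=None, sep="\t") -> ExpressionMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta = None
    if meta_path is not None:
        meta = read_metadata(meta_path, sep=sep)
        meta = meta.loc[df.index]
    return ExpressionMatrix(values=df.to_numpy(dtype=float),
                            gene_names=list(df.columns),
                            cell_ids=list(df.index.astype(str)),
                            meta=meta)


def write_expression_table(expr: ExpressionMatrix, path, sep="\t"):
    df = pd.DataFrame(expr.values, index=pd.Index(expr.cell_ids, name="cell_id"),
                      columns=expr.gene_names)
    df.to_csv(path, sep=sep)


def read_expression_mtx(mtx_path, genes_path, barcodes_path, meta_path=None,
                        sep="\t") -> ExpressionMatrix:
    """MatrixMarket cells x genes matrix with one gene / barcode name per line."""
    values = np.asarray(mmread(mtx_path).todense(), dtype=float)
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    meta = None
    if meta_path is not None:
        meta = read_metadata(meta_path, sep=sep).loc[barcodes]
    return ExpressionMatrix(values=values, gene_names=genes, cell_ids=barcodes, meta=meta)


def write_expression_mtx(expr: ExpressionMatrix, mtx_path, genes_path, barcodes_path):
    mmwrite(str(mtx_path), csr_matrix(expr.values))
    Path(genes_path).write_text("\n".join(expr.gene_names) + "\n")
    Path(barcodes_path).write_text("\n".join(expr.cell_ids) + "\n")


def read_metadata(path, sep="\t") -> pd.DataFrame:
    meta = pd.read_csv(path, sep=sep, index_col="cell_id")
    meta.index = meta.index.astype(str)
    return meta


def write_metadata(meta: pd.DataFrame, path, sep="\t"):
    meta.to_csv(path, sep=sep, index_label="cell_id")


def read_gene_set(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


def write_gene_set(genes, path):
    Path(path).write_text("\n".join(genes) + "\n")


def write_table(df: pd.DataFrame, path, sep="\t", **kwargs):
    df.to_csv(path, sep=sep, **kwargs)
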