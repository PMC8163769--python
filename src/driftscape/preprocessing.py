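"""From normalized expression to the model's state space.

The model operates on PCA projections of scaled (z-scored) expression of
variable genes. The linear path scaled-space -> PCA-space is kept exactly
invertible on the PCA span so that gene-level edits (the in-silico
perturbations) translate into analytic shifts of the model state:
editing gene g from value v to z moves the state by (z - v) * loadings[g].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class ExpressionMatrix:
    """Cells x genes normalized expression with per-cell metadata.

    ``meta`` rows align 1:1 with matrix rows and may carry ``time`` (real
    units, e.g. days), ``clone_id`` and ``cell_type`` columns.
    """

    values: np.ndarray
    gene_names: list
    cell_ids: list
    meta: pd.DataFrame = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.gene_names = list(self.gene_names)
        self.cell_ids = list(self.cell_ids)
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValueError("matrix shape does not match cell/gene name lengths")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        if len(self.meta) != len(self.cell_ids):
            raise ValueError("meta rows must align 1:1 with matrix rows")
        if "time" in self.meta.columns and not np.all(np.isfinite(self.meta["time"])):
            raise ValueError("time values must be finite")

    @property
    def n_cells(self):
        return self.values.shape[0]

    def subset_genes(self, genes: list) -> "ExpressionMatrix":
        idx = [self.gene_names.index(g) for g in genes]
        return ExpressionMatrix(self.values[:, idx], genes, self.cell_ids, self.meta)

    def subset_cells(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        ids = [c for c, m in zip(self.cell_ids, mask) if m]
        return ExpressionMatrix(self.values[mask], self.gene_names, ids,
                                self.meta.loc[mask].copy())


def select_variable_genes(expr: ExpressionMatrix, n_genes: int,
                          exclude: list | None = None) -> list:
    """Top ``n_genes`` genes by variance across cells.

    Ties are broken by gene-name lexicographic order; genes in ``exclude``
    (e.g. a cell-cycle-correlated list) are removed before ranking. When all
    genes are requested the original column order is restored.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    excluded = set(exclude or ())
    candidates = [g for g in expr.gene_names if g not in excluded]
    if n_genes > len(candidates):
        raise ValueError(f"n_genes={n_genes} exceeds the {len(candidates)} available genes")
    variances = expr.values.var(axis=0)
    var_of = {g: variances[i] for i, g in enumerate(expr.gene_names)}
    ranked = sorted(candidates, key=lambda g: (-var_of[g], g))
    chosen = set(ranked[:n_genes])
    return [g for g in expr.gene_names if g in chosen]


@dataclass
class ScalerParams:
    """Per-gene mean/sd fitted on a reference cell set (zero-sd genes flagged)."""

    genes: list
    mean: np.ndarray
    sd: np.ndarray

    @property
    def zero_variance(self) -> np.ndarray:
        return self.sd == 0


def fit_scaler(expr: ExpressionMatrix) -> ScalerParams:
    return ScalerParams(genes=list(expr.gene_names),
                        mean=expr.values.mean(axis=0),
                        sd=expr.values.std(axis=0, ddof=0))


def scale(expr: ExpressionMatrix, params: ScalerParams) -> np.ndarray:
    """Z-score per gene; genes with zero fitted sd map to 0."""
    if list(expr.gene_names) != list(params.genes):
        raise ValueError("gene mismatch between scaler and matrix")
    sd = np.where(params.sd > 0, params.sd, 1.0)
    z = (expr.values - params.mean) / sd
    z[:, params.zero_variance] = 0.0
    return z


@dataclass
class PCAProjection:
    """Orthonormal loadings (genes x k) and center of a fitted PCA."""

    loadings: np.ndarray
    center: np.ndarray
    k: int
    explained_variance: np.ndarray = None


def fit_pca(scaled: np.ndarray, k: int) -> PCAProjection:
    scaled = np.asarray(scaled, dtype=float)
    max_k = min(scaled.shape)
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; reducing", stacklevel=2)
        k = max_k
    p = PCA(n_components=k, svd_solver="full")
    p.fit(scaled)
    return PCAProjection(loadings=p.components_.T, center=p.mean_, k=k,
                         explained_variance=p.explained_variance_)


def project(scaled: np.ndarray, pca: PCAProjection) -> np.ndarray:
    return (np.asarray(scaled, dtype=float) - pca.center) @ pca.loadings


def back_project(states: np.ndarray, pca: PCAProjection) -> np.ndarray:
    return np.asarray(states, dtype=float) @ pca.loadings.T + pca.center


def save_projection_bundle(path, scaler: ScalerParams, pca: PCAProjection):
    np.savez(path, genes=np.array(scaler.genes), mean=scaler.mean, sd=scaler.sd,
             loadings=pca.loadings, center=pca.center,
             explained_variance=pca.explained_variance)


def load_projection_bundle(path):
    data = np.load(path, allow_pickle=False)
    scaler = ScalerParams(genes=[str(g) for g in data["genes"]],
                          mean=data["mean"], sd=data["sd"])
    pca = PCAProjection(loadings=data["loadings"], center=data["center"],
                        k=data["loadings"].shape[1],
                        explained_variance=data["explained_variance"])
    return scaler, pca
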