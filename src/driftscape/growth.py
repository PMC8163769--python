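"""Per-cell proliferation estimates.

Two routes to a cell's expected descendant count ``n`` over a real-time
interval:

* **empirical** — from clonal lineage barcodes: descendants of a cell in
  clone c between t_from and t_to are counted as
  (count(c, t_to) + pseudocount) / (count(c, t_from) + pseudocount),
  the pseudocount (default 1) guarding against barcode dropout;
* **signature** — from expression: per-cell birth/death scores are the mean
  z-scores of cell-cycle / apoptosis gene sets, smoothed over k-nearest
  neighbors in PCA space, then mapped through logistic functions to birth
  and death rates b, d in (L0, L0 + L). A birth-death process then gives

      g = b - d,     n = exp(dt_real * g).

The logistic steepness k is calibrated so that the logistic term at the
most extreme observed score is 0.001 of its range: k = ln(1000) / |s_min|.
Defaults L0 = 0.3, L = 1.2 bound the growth rate g in (-1.2, 1.2) per unit
real time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_L0 = 0.3
DEFAULT_L = 1.2
SMOOTH_K = 20
SMOOTH_BETA = 0.1
SMOOTH_ITERS = 5


@dataclass
class LogisticCalibration:
    """Parameters of the score -> rate logistic map."""

    L0: float = DEFAULT_L0
    L: float = DEFAULT_L
    k: float = 1.0
    s_min: float = None

    @classmethod
    def from_scores(cls, scores: np.ndarray, L0: float = DEFAULT_L0,
                    L: float = DEFAULT_L) -> "LogisticCalibration":
        """Set steepness from the score minimum: 0.001 = exp(-k |s_min|)."""
        s_min = float(np.min(scores))
        k = np.log(1000.0) / max(abs(s_min), 1e-12)
        return cls(L0=L0, L=L, k=k, s_min=s_min)


def empirical_descendants(meta: pd.DataFrame, t_from: float, t_to: float,
                          pseudocount: float = 1.0) -> pd.Series:
    """Expected descendants per t_from cell from clone barcode counts.

    Cells without a clone barcode (NaN clone_id) get n = 1.
    """
    if t_to <= t_from:
        raise ValueError("t_to must exceed t_from")
    at_from = meta[meta["time"] == t_from]
    at_to = meta[meta["time"] == t_to]
    counts_from = at_from["clone_id"].value_counts()
    counts_to = at_to["clone_id"].value_counts()
    n = pd.Series(1.0, index=at_from.index)
    has_clone = at_from["clone_id"].notna()
    clones = at_from.loc[has_clone, "clone_id"]
    num = clones.map(counts_to).fillna(0.0) + pseudocount
    den = clones.map(counts_from) + pseudocount
    n.loc[has_clone] = num / den
    return n


def signature_score(scaled: np.ndarray, genes: list, gene_set: list) -> np.ndarray:
    """Mean z-score over the gene-set genes present in the matrix."""
    present = [g for g in gene_set if g in genes]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    idx = [genes.index(g) for g in present]
    return np.asarray(scaled, dtype=float)[:, idx].mean(axis=1)


def smooth_scores(scores: np.ndarray, states: np.ndarray, k_nn: int = SMOOTH_K,
                  beta: float = SMOOTH_BETA, iters: int = SMOOTH_ITERS) -> np.ndarray:
    """Iterative k-NN smoothing: s_i <- beta s_i + (1-beta) mean(s_neighbors).

    Neighbors are the k_nn nearest cells by Euclidean distance in PCA space,
    excluding the cell itself; ties at equal distance break by cell index.
    The neighbor graph is fixed across iterations.
    """
    scores = np.asarray(scores, dtype=float).copy()
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if k_nn >= len(states):
        raise ValueError("need more cells than k_nn")
    from scipy.spatial.distance import cdist

    dist = cdist(states, states)
    np.fill_diagonal(dist, np.inf)  # the neighbor set excludes the cell itself
    order = np.argsort(dist, axis=1, kind="stable")  # ties break by cell index
    neighbors = order[:, :k_nn]
    for _ in range(iters):
        scores = beta * scores + (1.0 - beta) * scores[neighbors].mean(axis=1)
    return scores


def logistic_rates(scores: np.ndarray, calib: LogisticCalibration) -> np.ndarray:
    """rate = L0 + L / (1 + exp(-k s)); increasing in s, bounded in (L0, L0+L)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return calib.L0 + calib.L / (1.0 + np.exp(-calib.k * scores))


def descendants_from_growth(g: np.ndarray, dt_real: float) -> np.ndarray:
    """n = exp(dt_real * g) for growth rate g = b - d."""
    if dt_real <= 0:
        raise ValueError("dt_real must be positive")
    return np.exp(dt_real * np.asarray(g, dtype=float))


@dataclass
class GrowthTable:
    """Per-cell proliferation summary over a stated real-time interval."""

    cell_ids: list
    birth_score: np.ndarray
    death_score: np.ndarray
    birth_rate: np.ndarray
    death_rate: np.ndarray
    growth_rate: np.ndarray  # g = b - d
    n_descendants: np.ndarray  # exp(dt_real * g)
    dt_real: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"birth_score": self.birth_score, "death_score": self.death_score,
             "birth_rate": self.birth_rate, "death_rate": self.death_rate,
             "growth_rate": self.growth_rate, "n_descendants": self.n_descendants},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


def signature_growth_table(scaled: np.ndarray, genes: list, states: np.ndarray,
                           cell_ids: list, cycle_genes: list, apoptosis_genes: list,
                           dt_real: float, L0: float = DEFAULT_L0, L: float = DEFAULT_L,
                           k_nn: int = SMOOTH_K, beta: float = SMOOTH_BETA,
                           iters: int = SMOOTH_ITERS) -> GrowthTable:
    """Full signature pipeline: score -> smooth -> logistic rates -> n."""
    s_b = smooth_scores(signature_score(scaled, genes, cycle_genes), states,
                        k_nn=k_nn, beta=beta, iters=iters)
    s_d = smooth_scores(signature_score(scaled, genes, apoptosis_genes), states,
                        k_nn=k_nn, beta=beta, iters=iters)
    b = logistic_rates(s_b, LogisticCalibration.from_scores(s_b, L0=L0, L=L))
    d = logistic_rates(s_d, LogisticCalibration.from_scores(s_d, L0=L0, L=L))
    g = b - d
    return GrowthTable(cell_ids=list(cell_ids), birth_score=s_b, death_score=s_d,
                       birth_rate=b, death_rate=d, growth_rate=g,
                       n_descendants=descendants_from_growth(g, dt_real),
                       dt_real=dt_real)
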