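"""In-silico gene perturbations and fate-shift screens.

A perturbation sets the scaled (z-scored) expression of target genes to a
chosen z-value — negative for knockdown, positive for overexpression —
leaving all other genes untouched, then re-projects the edited profile
through the fitted PCA. Because the projection is linear, the state shift
is exactly sum_g (z - v_g) * loadings[g].

Screens simulate paired unperturbed/perturbed populations from the same
sampled cells with a shared noise stream, so with a no-op edit every fate
fraction difference is exactly zero. Shifts are quantified per repetition
as terminal fate fractions; significance by Welch's independent or paired
two-sided t-tests across repetitions, log2 fold-changes of the target-fate
fraction (floored at 1/(n_cells*n_reps) to stay finite), and
Benjamini-Hochberg FDR with the hit rule q < 0.01 and log2FC > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fate import FateClassifier, classify
from .potential import BasePotential, real_time_to_steps, sample_initial, simulate
from .preprocessing import PCAProjection, project

DEFAULT_Z_LADDER = (-2.5, -1.0, -0.5, 2.0, 5.0, 10.0)


@dataclass
class PerturbationSpec:
    """What to perturb and how to initialize the simulations."""

    genes: list
    z_value: float
    n_cells: int = 200
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_reps < 1:
            raise ValueError("n_cells and n_reps must be >= 1")


def apply_perturbation(scaled: np.ndarray, genes: list, spec: PerturbationSpec,
                       pca: PCAProjection) -> np.ndarray:
    """Set target genes to the spec's z-value and project to state space."""
    scaled = np.atleast_2d(np.asarray(scaled, dtype=float)).copy()
    for g in spec.genes:
        if g not in genes:
            raise KeyError(f"unknown gene {g!r}")
        scaled[:, genes.index(g)] = spec.z_value
    return project(scaled, pca)


def run_perturbation(model: BasePotential, spec: PerturbationSpec,
                     scaled_pool: np.ndarray, genes: list, pca: PCAProjection,
                     clf: FateClassifier, n_steps: int,
                     growth_weights: np.ndarray | None = None) -> pd.DataFrame:
    """Paired unperturbed/perturbed simulations over ``n_reps`` repetitions.

    Each repetition samples ``n_cells`` cells from the selector pool
    (with replacement, weighted by ``growth_weights`` when given), then
    simulates both arms from the same cells with an identical noise stream.
    Returns one row per repetition x arm with terminal fate fractions.
    """
    scaled_pool = np.atleast_2d(np.asarray(scaled_pool, dtype=float))
    if len(scaled_pool) == 0:
        raise ValueError("empty selector population")
    weights = growth_weights if growth_weights is not None else np.ones(len(scaled_pool))
    labels = [str(c) for c in clf._classes]
    rows = []
    for rep in range(spec.n_reps):
        rng = np.random.default_rng(spec.seed + rep)
        cells = sample_initial(scaled_pool, weights, spec.n_cells, rng)
        base_states = project(cells, pca)
        pert_states = apply_perturbation(cells, genes, spec, pca)
        noise = rng.standard_normal((n_steps, spec.n_cells, base_states.shape[1]))
        for arm, init in (("unperturbed", base_states), ("perturbed", pert_states)):
            terminal = simulate(model, init, n_steps, noise=noise).terminal
            assigned = classify(clf, terminal)
            row = {"rep": rep, "arm": arm}
            for lab in labels:
                row[lab] = float((assigned == lab).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def perturbation_stats(result: pd.DataFrame, target_fate: str,
                       mode: str = "paired", n_cells: int = 200) -> dict:
    """Two-sided t-test and log2 fold-change of the target-fate fraction.

    ``mode='independent'`` uses Welch's t-test; ``mode='paired'`` a paired
    t-test across repetitions (the screen convention). Identical arms give
    log2FC = 0 and p = 1 (the zero-variance paired case is reported as
    p = 1 with a flag).
    """
    unp = result[result["arm"] == "unperturbed"].sort_values("rep")[target_fate].to_numpy()
    per = result[result["arm"] == "perturbed"].sort_values("rep")[target_fate].to_numpy()
    if len(unp) < 2:
        raise ValueError("need >= 2 repetitions")
    degenerate = False
    if mode == "independent":
        t, p = stats.ttest_ind(per, unp, equal_var=False)
    elif mode == "paired":
        diff = per - unp
        if np.allclose(diff.std(ddof=1), 0.0):
            degenerate = True
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(per, unp)
    else:
        raise ValueError("mode must be 'independent' or 'paired'")
    if not np.isfinite(p):
        degenerate, t, p = True, 0.0, 1.0
    floor = 1.0 / (n_cells * len(unp))
    lfc = float(np.log2(max(per.mean(), floor) / max(unp.mean(), floor)))
    return {"t_stat": float(t), "p_value": float(p), "log2fc": lfc,
            "mean_perturbed": float(per.mean()), "mean_unperturbed": float(unp.mean()),
            "degenerate": degenerate}


def call_hits(screen: pd.DataFrame, fdr_threshold: float = 0.01,
              lfc_threshold: float = 0.5) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment per target fate; hit iff q < FDR and log2FC > threshold."""
    if ((screen["p_value"] < 0) | (screen["p_value"] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = screen.copy()
    out["q_value"] = np.nan
    for fate, idx in out.groupby("target_fate").groups.items():
        out.loc[idx, "q_value"] = multipletests(out.loc[idx, "p_value"], method="fdr_bh")[1]
    out["hit"] = (out["q_value"] < fdr_threshold) & (out["log2fc"] > lfc_threshold)
    return out


def run_screen(model: BasePotential, gene_list: list, z_value: float,
               scaled_pool: np.ndarray, genes: list, pca: PCAProjection,
               clf: FateClassifier, n_steps: int, target_fates: list,
               n_cells: int = 200, n_reps: int = 10, seed: int = 0,
               growth_weights: np.ndarray | None = None,
               mode: str = "paired") -> pd.DataFrame:
    """One row per screened gene x target fate, ready for :func:`call_hits`.

    The unperturbed arm uses the same seeds for every screened gene, so one
    reference arm per repetition is shared across the whole screen.
    """
    rows = []
    for gene in gene_list:
        spec = PerturbationSpec(genes=[gene], z_value=z_value,
                                n_cells=n_cells, n_reps=n_reps, seed=seed)
        result = run_perturbation(model, spec, scaled_pool, genes, pca, clf,
                                  n_steps, growth_weights=growth_weights)
        for fate in target_fates:
            st = perturbation_stats(result, fate, mode=mode, n_cells=n_cells)
            rows.append({"gene": gene, "target_fate": fate, **st})
    return pd.DataFrame(rows)


def temporal_perturbation(model: BasePotential, spec: PerturbationSpec,
                          pools_by_time: dict, genes: list, pca: PCAProjection,
                          clf: FateClassifier, t_final: float, target_fate: str,
                          growth_by_time: dict | None = None) -> pd.DataFrame:
    """Introduce the same perturbation at different initialization times.

    ``pools_by_time`` maps an initialization time to that snapshot's scaled
    expression pool. Later initializations are simulated for proportionally
    fewer steps to the shared final time. Returns the mean paired
    difference (perturbed - unperturbed) in the target-fate fraction per
    initialization time.
    """
    rows = []
    for t0, pool in sorted(pools_by_time.items()):
        if t0 >= t_final:
            raise ValueError("initialization time must precede the final time")
        n_steps = real_time_to_steps(t0, t_final, model.dt)
        weights = None if growth_by_time is None else growth_by_time[t0]
        result = run_perturbation(model, spec, pool, genes, pca, clf, n_steps,
                                  growth_weights=weights)
        unp = result[result["arm"] == "unperturbed"].sort_values("rep")[target_fate]
        per = result[result["arm"] == "perturbed"].sort_values("rep")[target_fate]
        diff = per.to_numpy() - unp.to_numpy()
        rows.append({"t_init": t0, "n_steps": n_steps,
                     "mean_difference": float(diff.mean()),
                     "sd_difference": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0})
    return pd.DataFrame(rows)
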