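"""Ground-truth fixtures: snapshots from known landscapes.

A population of cells evolves by the exact Euler-Maruyama discretization of
a known potential (quadratic or bistable double well) at a fine step size,
while branching: at each fine step a cell divides with probability
``birth_rate(x) * dt_fine``, descendants inheriting the parent's clone
barcode. The bistable default plants faster proliferation in the right
basin (x1 > 0), so clone barcode counts carry real growth signal.

Observed expression is a linear read-out of the latent state,
``expression = latent @ loadings.T + Gaussian noise``, with designated
blocks of genes loading positively / negatively on the fate axis x1. The
fixture ships toy "cycle" and "apoptosis" gene sets drawn from those
blocks, so signature-derived growth scores correlate with the planted
rates, and a designated fate-axis gene gives in-silico perturbations a
predictable direction. Fate labels are the terminal basin.

This generator emulates well-mixed cross-sectional snapshots only: no
count noise, dropout or library-size variation, and clones are observed
across snapshots (lineage-tracing style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .potential import DoubleWellPotential, QuadraticPotential
from .preprocessing import ExpressionMatrix


@dataclass
class LandscapeFixture:
    """Configuration of a synthetic study.

    Defaults define the standard desk-scale bistable benchmark:
    3 snapshots (days 0, 1, 2) of ~500 cells, 30 genes over a 2-D latent
    state, with 3x faster net growth in the right basin over the full
    time window.
    """

    potential: str = "bistable"  # "bistable" | "quadratic"
    well_scale: float = 1.0  # barrier steepness of the double well
    latent_dim: int = 2
    n_genes: int = 30
    snapshot_times: tuple = (0.0, 1.0, 2.0)
    cells_per_snapshot: int = 500
    n_initial: int = 500
    sigma: float = 0.1
    dt_fine: float = 0.02
    init_mode: str = "origin"  # "origin": uncommitted at the saddle; "bimodal": committed 50/50
    init_sd: float = 0.15
    expression_noise_sd: float = 0.1
    growth_left: float = 0.2  # birth rate in the left basin (per day)
    growth_ratio: float = 3.0  # descendant ratio right/left over the full window
    seed: int = 0

    def true_potential(self):
        if self.potential == "bistable":
            return DoubleWellPotential(k=self.latent_dim, a=self.well_scale,
                                       sigma=self.sigma, dt=self.dt_fine)
        if self.potential == "quadratic":
            return QuadraticPotential(k=self.latent_dim, sigma=self.sigma, dt=self.dt_fine)
        raise ValueError(f"unknown potential {self.potential!r}")

    @property
    def growth_right(self) -> float:
        span = self.snapshot_times[-1] - self.snapshot_times[0]
        return self.growth_left + np.log(self.growth_ratio) / span


@dataclass
class GroundTruth:
    """Everything the generator knows that real data would not reveal."""

    fixture: LandscapeFixture
    latent: np.ndarray  # per emitted cell, true latent state
    loadings: np.ndarray  # genes x latent_dim, full column rank
    birth_rate: np.ndarray  # per emitted cell, planted birth rate
    basin: np.ndarray  # per emitted cell, sign of x1 ("left"/"right")
    cycle_genes: list = field(default_factory=list)
    apoptosis_genes: list = field(default_factory=list)
    fate_gene: str = ""  # gene loading positively on the fate axis

    def latent_by_time(self, meta: pd.DataFrame, t: float) -> np.ndarray:
        return self.latent[(meta["time"] == t).to_numpy()]


def true_drift(fixture: LandscapeFixture, states: np.ndarray) -> np.ndarray:
    """Closed-form -grad Psi of the fixture's generating potential."""
    return fixture.true_potential().drift(states)


def _birth_rates(fixture: LandscapeFixture, x: np.ndarray) -> np.ndarray:
    if fixture.potential != "bistable":
        return np.full(len(x), fixture.growth_left)
    return np.where(x[:, 0] > 0, fixture.growth_right, fixture.growth_left)


def _loading_matrix(fixture: LandscapeFixture, rng: np.random.Generator) -> np.ndarray:
    """Structured gene loadings: thirds of the genes load +x1, -x1, and x2."""
    g, d = fixture.n_genes, fixture.latent_dim
    L = rng.normal(0.0, 0.1, size=(g, d))
    third = g // 3
    L[:third, 0] += 1.0  # "cycle" block: high in the right (fast-growing) basin
    L[third:2 * third, 0] -= 1.0  # "apoptosis" block: high in the left basin
    if d > 1:
        L[2 * third:, 1] += 1.0
    if np.linalg.matrix_rank(L) < d:
        raise ValueError("degenerate loading matrix")
    return L


def generate(fixture: LandscapeFixture):
    """Simulate the branching SDE and emit (ExpressionMatrix, GroundTruth).

    Snapshots subsample the living population (without replacement) to at
    most ``cells_per_snapshot`` cells; every emitted cell carries time,
    clone_id and a fate label (terminal basin for terminal-snapshot cells,
    "progenitor" before that).
    """
    if len(fixture.snapshot_times) < 2:
        raise ValueError("need at least 2 snapshot times")
    rng = np.random.default_rng(fixture.seed)
    model = fixture.true_potential()
    times = np.asarray(fixture.snapshot_times, dtype=float)
    dt = fixture.dt_fine
    scale = np.sqrt(2.0 * fixture.sigma**2 * dt)

    x = rng.normal(0.0, fixture.init_sd, size=(fixture.n_initial, fixture.latent_dim))
    if fixture.init_mode == "bimodal":
        # two already-specified progenitor subpopulations, one per basin
        x[:, 0] += rng.choice([-1.0, 1.0], size=fixture.n_initial)
    elif fixture.init_mode != "origin":
        raise ValueError(f"unknown init_mode {fixture.init_mode!r}")
    clone = np.arange(fixture.n_initial)

    snap_latent, snap_clone, snap_time = [], [], []

    def take_snapshot(t):
        m = min(fixture.cells_per_snapshot, len(x))
        idx = rng.choice(len(x), size=m, replace=False)
        snap_latent.append(x[idx].copy())
        snap_clone.append(clone[idx].copy())
        snap_time.append(np.full(m, t))

    t = times[0]
    take_snapshot(t)
    for t_next in times[1:]:
        n_steps = int(round((t_next - t) / dt))
        for _ in range(n_steps):
            x = x + model.drift(x) * dt + scale * rng.standard_normal(x.shape)
            births = rng.random(len(x)) < _birth_rates(fixture, x) * dt
            if births.any():
                x = np.vstack([x, x[births]])
                clone = np.concatenate([clone, clone[births]])
        t = t_next
        take_snapshot(t)

    latent = np.vstack(snap_latent)
    clone_ids = np.concatenate(snap_clone)
    time_col = np.concatenate(snap_time)
    basin = np.where(latent[:, 0] > 0, "right", "left")
    is_terminal = time_col == times[-1]
    fate = np.where(is_terminal, basin, "progenitor")

    loadings = _loading_matrix(fixture, rng)
    expression = latent @ loadings.T + rng.normal(
        0.0, fixture.expression_noise_sd, size=(len(latent), fixture.n_genes))

    gene_names = [f"g{i:03d}" for i in range(fixture.n_genes)]
    cell_ids = [f"c{i:05d}" for i in range(len(latent))]
    meta = pd.DataFrame({"time": time_col, "clone_id": clone_ids, "cell_type": fate},
                        index=pd.Index(cell_ids, name="cell_id"))
    expr = ExpressionMatrix(values=expression, gene_names=gene_names,
                            cell_ids=cell_ids, meta=meta)

    third = fixture.n_genes // 3
    truth = GroundTruth(
        fixture=fixture, latent=latent, loadings=loadings,
        birth_rate=_birth_rates(fixture, latent), basin=basin,
        cycle_genes=gene_names[:min(5, third)],
        apoptosis_genes=gene_names[third:third + min(5, third)],
        fate_gene=gene_names[0],
    )
    return expr, truth
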