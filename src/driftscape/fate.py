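"""Clonal fate-bias prediction from simulated trajectories.

For each clone's starting cell, many independent trajectories are simulated
to the final timepoint; terminal states are assigned cell-type labels by a
k-nearest-neighbor classifier over reference states, and the clonal fate
bias between two target fates A and B (e.g. neutrophil vs monocyte) is

    bias = (count_A + pseudocount) / (count_A + count_B + 2 * pseudocount),

so a clone in which neither fate is ever reached scores exactly 0.5.
Predictions are ensembled over training checkpoints by taking the mean,
and scored against lineage-tracing ground truth by Pearson correlation and
by the AUROC of calling bias > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .potential import BasePotential, simulate


@dataclass
class FateClassifier:
    """k-NN majority-vote cell-type classifier in PCA space.

    The exact neighbor search is the reference backend (an approximate
    index may substitute provided it agrees with exact k-NN on >= 99% of
    queries); ties in the vote break by lexicographic label order.
    """

    reference: np.ndarray
    labels: np.ndarray
    k: int = 20
    _index: NearestNeighbors = field(default=None, repr=False)
    _classes: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        self.labels = np.asarray(self.labels)
        if len(self.reference) == 0:
            raise ValueError("empty reference")
        if len(self.reference) < self.k:
            raise ValueError("need at least k reference points")
        self._classes = np.unique(self.labels)  # sorted: defines tie order
        self._index = NearestNeighbors(n_neighbors=self.k).fit(self.reference)


def fit_classifier(reference: np.ndarray, labels, k: int = 20) -> FateClassifier:
    return FateClassifier(reference=reference, labels=labels, k=k)


def classify(clf: FateClassifier, states: np.ndarray) -> np.ndarray:
    states = np.atleast_2d(np.asarray(states, dtype=float))
    _, idx = clf._index.kneighbors(states)
    neighbor_labels = clf.labels[idx]  # (n, k)
    # vote counts per class; argmax over sorted classes breaks ties deterministically
    counts = np.stack([(neighbor_labels == c).sum(axis=1) for c in clf._classes], axis=1)
    return clf._classes[np.argmax(counts, axis=1)]


def clonal_fate_bias(counts_a: float, counts_b: float, pseudocount: float = 1.0) -> float:
    """Pseudocounted share of fate A among fates A and B."""
    if counts_a < 0 or counts_b < 0:
        raise ValueError("counts must be nonnegative")
    return (counts_a + pseudocount) / (counts_a + counts_b + 2.0 * pseudocount)


@dataclass
class FateOutcome:
    """Terminal-fate tally of one clone's simulated trajectories."""

    counts: dict
    n_trajectories: int
    bias: float
    hit_any_target: bool  # >= 1 trajectory reached either target fate
    fate_a: str = ""
    fate_b: str = ""


def predict_fate(model: BasePotential, initial_cell: np.ndarray, clf: FateClassifier,
                 n_steps: int, fate_a, fate_b, n_traj: int = 2000,
                 pseudocount: float = 1.0, seed: int = 0) -> FateOutcome:
    """Simulate ``n_traj`` trajectories from copies of one starting cell."""
    initial_cell = np.asarray(initial_cell, dtype=float).reshape(1, -1)
    init = np.repeat(initial_cell, n_traj, axis=0)
    traj = simulate(model, init, n_steps, seed=seed)
    labels = classify(clf, traj.terminal)
    classes, tallies = np.unique(labels, return_counts=True)
    counts = {str(c): int(n) for c, n in zip(classes, tallies)}
    c_a = counts.get(str(fate_a), 0)
    c_b = counts.get(str(fate_b), 0)
    return FateOutcome(counts=counts, n_trajectories=n_traj,
                       bias=clonal_fate_bias(c_a, c_b, pseudocount),
                       hit_any_target=(c_a + c_b) > 0,
                       fate_a=str(fate_a), fate_b=str(fate_b))


def terminal_mass_fractions(model: BasePotential, init: np.ndarray, n_steps: int,
                            label_fn, growth_rate_fn=None, seed: int = 0) -> dict:
    """Predicted terminal population composition, with optional proliferation.

    Simulates the population and tallies terminal labels. A model that
    accounts for proliferation weights every trajectory by its accumulated
    lineage mass exp(sum_t g(x_t) * dt) — the branching-diffusion prediction
    of how many descendants that trajectory's lineage contributes — so
    fast-growing branches claim a larger share of the terminal population.
    Without ``growth_rate_fn`` all trajectories weigh 1 (cell-count
    fractions).
    """
    traj = simulate(model, init, n_steps, seed=seed)
    if growth_rate_fn is None:
        mass = np.ones(traj.terminal.shape[0])
    else:
        integral = sum(np.asarray(growth_rate_fn(traj.states[t]), dtype=float)
                       for t in range(n_steps)) * model.dt
        mass = np.exp(integral)
    labels = np.asarray(label_fn(traj.terminal))
    total = mass.sum()
    return {str(lab): float(mass[labels == lab].sum() / total)
            for lab in np.unique(labels)}


def ensemble_bias(per_checkpoint_biases) -> float:
    """Mean fate bias across the last evaluated checkpoints."""
    biases = np.asarray(list(per_checkpoint_biases), dtype=float)
    if biases.size == 0:
        raise ValueError("no checkpoint biases to ensemble")
    return float(biases.mean())


def score_predictions(predicted, actual) -> dict:
    """Pearson r and AUROC (positives: actual bias > 0.5) of bias predictions."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if len(predicted) != len(actual):
        raise ValueError("length mismatch")
    if len(predicted) < 3:
        raise ValueError("need at least 3 clones to score")
    if np.std(actual) == 0:
        raise ValueError("actual biases are constant; correlation undefined")
    if np.std(predicted) == 0:
        r = np.nan  # constant predictor: correlation undefined, AUROC still 0.5
    else:
        r = float(pearsonr(predicted, actual)[0])
    positives = (actual > 0.5).astype(int)
    auroc = float(roc_auc_score(positives, predicted))
    return {"pearson_r": r, "auroc": auroc}
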