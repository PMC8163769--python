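"""Scalar potential over cell-state space, its drift field, and SDE simulation.

A cell's state x in R^k evolves by the diffusion

    dX = mu(X) dt + sqrt(2 sigma^2) dW,      mu(x) = -grad Psi(x),

simulated with the first-order (Euler-Maruyama) discretization

    X(t + dt) = X(t) + mu(X(t)) dt + sqrt(2 sigma^2 dt) Z,   Z ~ N(0, I).

``MLPPotential`` parameterizes Psi with a fully connected softplus network
(default 2 hidden layers x 400 units); the drift is the exact analytic
input-gradient of the network, so it agrees with finite differences of the
potential to solver precision. Analytic potentials (quadratic well,
double well) share the same interface and serve as closed-form references.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import _autodiff as ad

# process constants used throughout unless overridden
DEFAULT_SIGMA = 0.1
DEFAULT_DT = 0.1
DEFAULT_TAU = 1e-6


@dataclass
class Trajectory:
    """States of a simulated population: (n_steps+1, n_cells, k)."""

    states: np.ndarray
    t0: float
    dt: float
    seed: int | None = None

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]


class BasePotential:
    """Interface shared by learned and analytic potentials."""

    sigma: float
    dt: float
    k: int

    def potential(self, states: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def drift(self, states: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MLPPotential(BasePotential):
    """Softplus MLP potential with exact analytic drift.

    Parameters
    ----------
    k : state dimension.
    hidden : hidden layer widths (default (400, 400)).
    sigma, dt : noise scale and simulation step size (default 0.1 each).
    tau : entropic-regularizer strength in the training objective.
    seed : initialization seed (weights ~ N(0, 1/fan_in)).
    """

    def __init__(self, k: int, hidden: tuple = (400, 400),
                 sigma: float = DEFAULT_SIGMA, dt: float = DEFAULT_DT,
                 tau: float = DEFAULT_TAU, seed: int = 0):
        self.k = int(k)
        self.hidden = tuple(int(h) for h in hidden)
        self.sigma = float(sigma)
        self.dt = float(dt)
        self.tau = float(tau)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = [self.k, *self.hidden, 1]
        self.params: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.params.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    # ---- numpy fast paths ---------------------------------------------------

    def _check(self, states):
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if states.shape[1] != self.k:
            raise ValueError(f"states have dimension {states.shape[1]}, expected {self.k}")
        return states

    def potential(self, states: np.ndarray) -> np.ndarray:
        x = self._check(states)
        n_hidden = len(self.hidden)
        h = x
        for layer in range(n_hidden):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            h = np.logaddexp(0.0, h @ W + b)
        W, b = self.params[2 * n_hidden], self.params[2 * n_hidden + 1]
        return (h @ W + b).ravel()

    def drift(self, states: np.ndarray) -> np.ndarray:
        """mu(x) = -grad Psi(x), via the analytic backward pass of the MLP."""
        x = self._check(states)
        n_hidden = len(self.hidden)
        pre = []  # pre-activations per hidden layer
        h = x
        for layer in range(n_hidden):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            z = h @ W + b
            pre.append(z)
            h = np.logaddexp(0.0, z)
        W_out = self.params[2 * n_hidden]
        g = np.broadcast_to(W_out.T, (len(x), W_out.shape[0])).copy()
        for layer in reversed(range(n_hidden)):
            W = self.params[2 * layer]
            g = (g * expit(pre[layer])) @ W.T
        return -g

    # ---- tape versions for training ----------------------------------------

    def param_tensors(self) -> list[ad.Tensor]:
        return [ad.Tensor(p) for p in self.params]

    def potential_expr(self, params: list[ad.Tensor], x: ad.Tensor) -> ad.Tensor:
        n_hidden = len(self.hidden)
        h = x
        for layer in range(n_hidden):
            h = ad.softplus(h @ params[2 * layer] + params[2 * layer + 1])
        return h @ params[2 * n_hidden] + params[2 * n_hidden + 1]

    def drift_expr(self, params: list[ad.Tensor], x: ad.Tensor) -> ad.Tensor:
        """Drift as an explicit first-order expression in weights and states."""
        n_hidden = len(self.hidden)
        pre = []
        h = x
        for layer in range(n_hidden):
            z = h @ params[2 * layer] + params[2 * layer + 1]
            pre.append(z)
            h = ad.softplus(z)
        g = params[2 * n_hidden].T  # (1, H), broadcasts over the batch
        for layer in reversed(range(n_hidden)):
            g = (ad.sigmoid(pre[layer]) * g) @ params[2 * layer].T
        return -g

    def set_params(self, params: list[np.ndarray]):
        self.params = [np.array(p, dtype=float, copy=True) for p in params]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    # ---- checkpointing ------------------------------------------------------

    def save(self, path):
        config = dict(k=self.k, hidden=list(self.hidden), sigma=self.sigma,
                      dt=self.dt, tau=self.tau, seed=self.seed)
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez(path, config=json.dumps(config), **arrays)

    @classmethod
    def load(cls, path) -> "MLPPotential":
        data = np.load(path, allow_pickle=False)
        config = json.loads(str(data["config"]))
        model = cls(k=config["k"], hidden=tuple(config["hidden"]), sigma=config["sigma"],
                    dt=config["dt"], tau=config["tau"], seed=config["seed"])
        model.params = [data[f"param_{i}"] for i in range(len(model.params))]
        return model


class QuadraticPotential(BasePotential):
    """Psi(x) = ||x||^2 / 2; drift -x. The Ornstein-Uhlenbeck reference."""

    def __init__(self, k: int, sigma: float = DEFAULT_SIGMA, dt: float = DEFAULT_DT):
        self.k, self.sigma, self.dt = int(k), float(sigma), float(dt)

    def potential(self, states):
        x = np.atleast_2d(states)
        return 0.5 * (x**2).sum(axis=1)

    def drift(self, states):
        return -np.atleast_2d(np.asarray(states, dtype=float))


class DoubleWellPotential(BasePotential):
    """Bistable landscape: Psi(x) = a (x1^2 - 1)^2 / 4 + sum_{j>1} x_j^2 / 2.

    Two basins at x1 = +/-1 separated by a barrier at x1 = 0; the remaining
    coordinates are simple harmonic. ``a`` scales the barrier height.
    """

    def __init__(self, k: int = 2, a: float = 1.0,
                 sigma: float = DEFAULT_SIGMA, dt: float = DEFAULT_DT):
        self.k, self.a = int(k), float(a)
        self.sigma, self.dt = float(sigma), float(dt)

    def potential(self, states):
        x = np.atleast_2d(states)
        return self.a * (x[:, 0]**2 - 1.0)**2 / 4.0 + 0.5 * (x[:, 1:]**2).sum(axis=1)

    def drift(self, states):
        x = np.atleast_2d(np.asarray(states, dtype=float))
        mu = -x.copy()
        mu[:, 0] = -self.a * (x[:, 0]**3 - x[:, 0])
        return mu


def simulate(model: BasePotential, init: np.ndarray, n_steps: int,
             seed: int | None = None, noise: np.ndarray | None = None,
             t0: float = 0.0) -> Trajectory:
    """Euler-Maruyama simulation of a population of cells.

    Parameters
    ----------
    init : (n_cells, k) initial states; the returned trajectory starts with
        an exact copy of this population.
    n_steps : number of discretization steps of size ``model.dt``.
    seed : seeds an i.i.d. standard-normal noise stream (per step, cell and
        coordinate). Ignored if ``noise`` is given.
    noise : optional (n_steps, n_cells, k) standard-normal array; passing the
        same array to paired simulations shares their noise stream exactly.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    n_cells, k = init.shape
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if noise is None:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_steps, n_cells, k))
    scale = np.sqrt(2.0 * model.sigma**2 * model.dt)
    states = np.empty((n_steps + 1, n_cells, k))
    states[0] = init
    x = init
    for step in range(n_steps):
        x = x + model.drift(x) * model.dt + scale * noise[step]
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite states at simulation step {step + 1}")
        states[step + 1] = x
    return Trajectory(states=states, t0=t0, dt=model.dt, seed=seed)


def sample_initial(population: np.ndarray, weights: np.ndarray, n_cells: int,
                   rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw initial cells with replacement, probability proportional to weights.

    Used to seed simulations from an observed snapshot with sampling biased
    toward proliferative cells (weights = expected descendant counts).
    """
    population = np.atleast_2d(np.asarray(population, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.choice(len(population), size=n_cells, replace=True, p=weights / total)
    return population[idx]


def real_time_to_steps(t_from: float, t_to: float, dt: float) -> int:
    """Number of discretization steps spanning a real-time interval."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_to <= t_from:
        raise ValueError("t_to must exceed t_from")
    span = t_to - t_from
    n_steps = int(round(span / dt))
    if abs(n_steps * dt - span) > 1e-9 * max(1.0, span):
        warnings.warn(
            f"interval {span} is not an integer multiple of dt={dt}; using {n_steps} steps",
            stacklevel=2,
        )
    return max(n_steps, 1)


def grid_visualize(model: BasePotential, bounds, resolution: int,
                   embedding_map=None):
    """Potential values and unit drift arrows on a uniform grid.

    ``bounds`` is ((x_min, x_max), (y_min, y_max)) in a 2-D embedding;
    ``embedding_map`` optionally lifts grid points into the model's state
    space before evaluation (identity for 2-D models). Returns
    (grid_points (r*r, 2), potential values (r*r,), unit drift (r*r, 2)).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    (x0, x1), (y0, y1) = bounds
    if not all(np.isfinite([x0, x1, y0, y1])):
        raise ValueError("bounds must be finite")
    xs = np.linspace(x0, x1, resolution)
    ys = np.linspace(y0, y1, resolution)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    lifted = grid if embedding_map is None else embedding_map(grid)
    psi = model.potential(lifted)
    mu = model.drift(lifted)[:, :2]
    norms = np.linalg.norm(mu, axis=1, keepdims=True)
    arrows = np.divide(mu, norms, out=np.zeros_like(mu), where=norms > 0)
    return grid, psi, arrows
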