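"""Fitting the potential to time-series snapshots.

The objective sums, over consecutive snapshot pairs (t_i, t_{i+1}), the
(squared, debiased) Sinkhorn divergence between a population simulated
forward from the empirical t_i batch and the empirical t_{i+1} batch, with
source masses proportional to each simulated cell's expected descendant
count, plus an entropic regularizer tau * sum_j Psi(x_j) / sigma^2 over the
final observed snapshot (which the model treats as near steady state).

Optimization is Adam on a per-epoch random batch (default 1/10 of each
snapshot), with the learning rate multiplied by 0.9 every 100 steps and
gradient clipping at global max-norm 0.1. Before the main phase the
potential is pretrained by contrastive divergence on the final snapshot:
treating p(x) proportional to exp(-Psi(x)/sigma^2), each step lowers Psi at
data samples and raises it at negative samples obtained by one
Euler-Maruyama step from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .potential import MLPPotential, real_time_to_steps, sample_initial, simulate
from .transport import (WeightedCloud, entropic_plan, interpolate_midpoint,
                        sinkhorn_divergence, weighted_marginals_from_growth)


@dataclass
class SnapshotDataset:
    """Per-snapshot cell states in model space with real-time labels.

    ``growth_rates[i]`` optionally holds per-cell growth rates g (per unit
    real time) for snapshot i; expected descendants over an interval dt are
    then exp(g * dt).
    """

    times: list
    states: list
    growth_rates: list = None

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")
        if sorted(self.times) != list(self.times):
            raise ValueError("snapshot times must be sorted")
        self.states = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.states]

    @property
    def n_snapshots(self):
        return len(self.times)

    def growth_for(self, i: int) -> np.ndarray | None:
        if self.growth_rates is None:
            return None
        return self.growth_rates[i]


@dataclass
class TrainingConfig:
    epochs: int = 2500
    batch_frac: float = 0.1
    lr: float = 0.01
    lr_decay: float = 0.9
    lr_decay_every: int = 100
    clip_norm: float = 0.1
    pretrain_steps: int = 500
    pretrain_lr: float = 1e-9
    blur: float = 0.1
    scaling: float = 0.7
    seed: int = 0
    eval_every: int = 500
    use_growth_weights: bool = True
    # The entropic divergence under squared-Euclidean cost already estimates
    # the *squared* 2-Wasserstein distance, so it enters the loss as-is;
    # set True to square it once more.
    square_divergence: bool = False
    sinkhorn_tol: float = 1e-2
    sinkhorn_max_iter: int = 50
    chain_from_first: bool = False  # simulate once from t_1 through all snapshots

    def __post_init__(self):
        if not (0 < self.batch_frac <= 1):
            raise ValueError("batch_frac must be in (0, 1]")
        for name in ("epochs", "lr_decay", "lr_decay_every", "clip_norm",
                     "blur", "scaling", "eval_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr < 0:  # lr == 0 freezes the optimizer, which is a valid contract
            raise ValueError("lr must be nonnegative")


@dataclass
class TrainingState:
    epochs: list = field(default_factory=list)
    losses: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)  # (epoch, params copy)
    lr_trace: list = field(default_factory=list)


class Adam:
    """Adam optimizer over a list of numpy parameter arrays."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _clip_global_norm(grads, max_norm):
    total = np.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        grads = [g * scale for g in grads]
    return grads


def _batch_indices(rng, n, frac):
    size = min(n, max(2, int(round(frac * n))))
    return rng.choice(n, size=size, replace=False)


def _simulate_tape(model, params_t, x0, n_steps, noise):
    """Euler-Maruyama recursion on the autodiff tape; returns terminal Tensor."""
    scale = np.sqrt(2.0 * model.sigma**2 * model.dt)
    x = x0 if isinstance(x0, ad.Tensor) else ad.Tensor(x0)
    for step in range(n_steps):
        x = x + model.drift_expr(params_t, x) * model.dt + ad.Tensor(scale * noise[step])
    return x


def objective(model: MLPPotential, snapshots: SnapshotDataset,
              config: TrainingConfig, rng: np.random.Generator,
              params_t: list | None = None) -> ad.Tensor:
    """One stochastic evaluation of the training loss as a scalar tape node.

    Backpropagating through the returned node yields exact gradients with
    respect to ``params_t`` (defaults to fresh tensors of the model's
    current parameters). The Sinkhorn divergence enters through its
    envelope gradient with respect to the simulated terminal states.
    """
    if snapshots.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    if params_t is None:
        params_t = model.param_tensors()
    total = None
    carried = None  # terminal states of the previous pair when chaining
    for i in range(snapshots.n_snapshots - 1):
        t_i, t_next = snapshots.times[i], snapshots.times[i + 1]
        n_steps = real_time_to_steps(t_i, t_next, model.dt)
        if config.chain_from_first and carried is not None:
            x0 = carried
            alpha = None
        else:
            src = snapshots.states[i]
            idx = _batch_indices(rng, len(src), config.batch_frac)
            x0 = src[idx]
            g = snapshots.growth_for(i)
            alpha = None
            if config.use_growth_weights and g is not None:
                alpha = weighted_marginals_from_growth(np.exp(g[idx] * (t_next - t_i)))
        tgt = snapshots.states[i + 1]
        tgt_batch = tgt[_batch_indices(rng, len(tgt), config.batch_frac)]
        n_cells = x0.value.shape[0] if isinstance(x0, ad.Tensor) else len(x0)
        noise = rng.standard_normal((n_steps, n_cells, model.k))
        x_T = _simulate_tape(model, params_t, x0, n_steps, noise)
        if config.chain_from_first:
            carried = x_T
        value, grad = sinkhorn_divergence(
            WeightedCloud(x_T.value, alpha), WeightedCloud(tgt_batch),
            blur=config.blur, scaling=config.scaling, return_grad=True,
            tol=config.sinkhorn_tol, max_iter=config.sinkhorn_max_iter)
        node = ad.external_grad(x_T, value, grad)
        term = node * node if config.square_divergence else node
        total = term if total is None else total + term
    if model.tau != 0:
        final = snapshots.states[-1]
        fb = final[_batch_indices(rng, len(final), config.batch_frac)]
        psi_sum = model.potential_expr(params_t, ad.Tensor(fb)).sum()
        total = total + psi_sum * (model.tau / model.sigma**2)
    if not np.isfinite(total.value):
        raise FloatingPointError("non-finite training loss")
    return total


def pretrain(model: MLPPotential, final_snapshot: np.ndarray, steps: int,
             lr: float = 1e-9, seed: int = 0, batch_frac: float = 1.0) -> MLPPotential:
    """Contrastive-divergence initialization of the potential (in place).

    CD-1 with a Langevin-style proposal: negatives are one Euler-Maruyama
    step from the data under the current drift. With zero steps the
    parameters are untouched.
    """
    data = np.atleast_2d(np.asarray(final_snapshot, dtype=float))
    if len(data) == 0:
        raise ValueError("final snapshot is empty")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(2.0 * model.sigma**2 * model.dt)
    for _ in range(steps):
        idx = _batch_indices(rng, len(data), batch_frac)
        batch = data[idx]
        neg = batch + model.drift(batch) * model.dt + scale * rng.standard_normal(batch.shape)
        params_t = model.param_tensors()
        pos_term = model.potential_expr(params_t, ad.Tensor(batch)).mean()
        neg_term = model.potential_expr(params_t, ad.Tensor(neg)).mean()
        loss = (pos_term - neg_term) / model.sigma**2
        if not np.isfinite(loss.value):
            raise FloatingPointError("pretraining loss diverged")
        loss.backward()
        grads = [t.grad if t.grad is not None else np.zeros_like(t.value)
                 for t in params_t]
        for p, g in zip(model.params, grads):
            p -= lr * g
    return model


def train(model: MLPPotential, snapshots: SnapshotDataset,
          config: TrainingConfig, checkpoint_dir=None) -> TrainingState:
    """Pretrain then run the main Adam loop; records losses and checkpoints."""
    pretrain(model, snapshots.states[-1], config.pretrain_steps,
             lr=config.pretrain_lr, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params, lr=config.lr)
    state = TrainingState()
    for epoch in range(1, config.epochs + 1):
        params_t = model.param_tensors()
        loss = objective(model, snapshots, config, rng, params_t=params_t)
        loss.backward()
        grads = [t.grad if t.grad is not None else np.zeros_like(t.value)
                 for t in params_t]
        grads = _clip_global_norm(grads, config.clip_norm)
        opt.step(model.params, grads)
        if opt.t % config.lr_decay_every == 0:
            opt.lr *= config.lr_decay
        state.epochs.append(epoch)
        state.losses.append(float(loss.value))
        state.lr_trace.append(opt.lr)
        if epoch % config.eval_every == 0 or epoch == config.epochs:
            if not state.checkpoints or state.checkpoints[-1][0] != epoch:
                state.checkpoints.append((epoch, model.copy_params()))
                if checkpoint_dir is not None:
                    model.save(f"{checkpoint_dir}/checkpoint_epoch{epoch:05d}.npz")
    return state


def evaluate_heldout(model: MLPPotential, snapshots: SnapshotDataset,
                     held_out_time: float, growth_n: np.ndarray | None = None,
                     n_sim: int = 10000, seed: int = 0,
                     checkpoints: list | None = None,
                     blur: float = 0.1, scaling: float = 0.7,
                     tol: float = 1e-2, max_iter: int = 50) -> dict:
    """Held-out timepoint recovery with the OT-midpoint baseline.

    ``snapshots`` here contains the *full* data including the held-out
    snapshot; the model is assumed trained on the others. For each
    checkpoint, ``n_sim`` cells are resampled with replacement from the
    first snapshot (weighted by ``growth_n`` when given), simulated to the
    held-out and final times, and compared to the empirical populations by
    Sinkhorn divergence. The testing distance is reported for the
    checkpoint with the lowest training distance.
    """
    times = list(snapshots.times)
    if held_out_time not in times:
        raise ValueError("held-out time not among snapshot times")
    h = times.index(held_out_time)
    if h == 0 or h == len(times) - 1:
        raise ValueError("held-out time must lie strictly between training snapshots")
    first, last = snapshots.states[0], snapshots.states[-1]
    held = snapshots.states[h]
    weights = growth_n if growth_n is not None else np.ones(len(first))
    rng = np.random.default_rng(seed)
    if checkpoints is None:
        checkpoints = [(None, model.copy_params())]

    steps_to_h = real_time_to_steps(times[0], held_out_time, model.dt)
    steps_to_T = real_time_to_steps(times[0], times[-1], model.dt)
    records = []
    for epoch, params in checkpoints:
        model.set_params(params)
        init = sample_initial(first, weights, n_sim, rng)
        traj = simulate(model, init, steps_to_T, seed=int(rng.integers(2**31)))
        test_d = sinkhorn_divergence(WeightedCloud(traj.states[steps_to_h]),
                                     WeightedCloud(held), blur=blur, scaling=scaling,
                                     tol=tol, max_iter=max_iter)
        train_d = sinkhorn_divergence(WeightedCloud(traj.terminal),
                                      WeightedCloud(last), blur=blur, scaling=scaling,
                                      tol=tol, max_iter=max_iter)
        records.append({"epoch": epoch, "train_distance": train_d,
                        "test_distance": test_d})

    best = min(records, key=lambda r: r["train_distance"])

    # OT-midpoint interpolation baseline between the flanking snapshots
    alpha = weighted_marginals_from_growth(weights)
    plan = entropic_plan(WeightedCloud(first, alpha), WeightedCloud(last),
                         blur=blur, scaling=scaling, tol=tol, max_iter=max_iter)
    interp = interpolate_midpoint(WeightedCloud(first, alpha), WeightedCloud(last),
                                  plan, n_sim, rng)
    baseline = sinkhorn_divergence(WeightedCloud(interp), WeightedCloud(held),
                                   blur=blur, scaling=scaling, tol=tol, max_iter=max_iter)
    return {"records": records, "selected": best,
            "test_distance": best["test_distance"],
            "train_distance": best["train_distance"],
            "baseline_distance": baseline}
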