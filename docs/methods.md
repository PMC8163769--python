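# Methods

## Model

A cell's state is a point `x` in a k-dimensional space (PCA coordinates of
z-scored variable-gene expression, or any user-supplied embedding). Its
evolution is the diffusion

    dX(t) = mu(X(t)) dt + sqrt(2 sigma^2) dW(t),     mu(x) = -grad Psi(x),

simulated by first-order (Euler–Maruyama) discretization with step `dt`:

    X(t + dt) = X(t) + mu(X(t)) dt + sqrt(2 sigma^2 dt) Z,   Z ~ N(0, I).

`Psi` is a fully connected scalar-output network with softplus activations
(default two hidden layers of 400 units; widths are configurable and the
desk-scale experiments below use 2x64). The drift is the exact analytic
input-gradient of the network — written out explicitly as a first-order
expression in the weights — so it matches finite differences of `Psi` to
solver precision, and a single reverse-mode sweep of the in-package
autodiff engine yields exact parameter gradients of losses evaluated on
simulated trajectories. Noise is isotropic and constant.

## Objective

Given snapshots at real times `t_1 < ... < t_n`, each training step draws a
batch (default 1/10 of each snapshot) from snapshot `i`, simulates it
forward `(t_{i+1} - t_i)/dt` Euler steps, and measures the debiased
entropic divergence against a batch of snapshot `i+1` under squared
Euclidean cost. Source masses `alpha_j` are proportional to each cell's
expected descendant count over the interval; target masses are uniform.
The loss sums these divergences over consecutive pairs and adds the
regularizer `tau * sum_j Psi(x_j) / sigma^2` over the final snapshot,
which encodes the assumption that the last timepoint is near steady state
(low potential where terminal cells accumulate).

The entropic divergence with squared-Euclidean ground cost is itself an
estimate of the *squared* 2-Wasserstein distance, so it enters the loss
directly; a flag (`square_divergence`) squares it once more for users who
want the quartic variant, but the default is the faithful squared-distance
objective. Empirically the quartic variant shrinks transport gradients as
the fit improves until the `tau` term dominates under Adam and distorts
the landscape, which is the main reason it is not the default.

Optimization is Adam with gradient clipping at global max-norm 0.1 and a
learning-rate schedule that multiplies by 0.9 every 100 steps (one batch
per epoch, so steps and epochs coincide). The default initial rate is
0.01; smaller rates are advisable when training diverges. Before the main
phase, the potential is initialized by contrastive divergence on the final
snapshot: treating `p(x) ~ exp(-Psi(x)/sigma^2)`, each step lowers `Psi`
at data samples and raises it at negatives produced by one Euler–Maruyama
step from the data (CD-1), with plain SGD at a deliberately tiny default
rate (1e-9).

Defaults for the process constants: `sigma = dt = 0.1` (real-time units of
the data, e.g. days), `tau = 1e-6`, Sinkhorn `blur = 0.1` and annealing
`scaling = 0.7`, 2500 epochs with evaluation every 500. These constants
couple to the scale of the state space: `sigma` is an absolute noise
amplitude and `blur` an absolute resolution length, so state coordinates
should live on a scale where typical inter-population displacements are
O(1)–O(10). A caution specific to `tau`: under Adam the regularizer is a
persistent directional gradient, and over long runs it progressively
deepens the potential under the densest terminal regions; at desk scale
this becomes visible (and eventually destroys barrier structure) beyond
roughly 400–600 epochs, which is one reason the scaled-down experiments
train for 300.

## Entropic optimal transport

`transport` implements a log-domain Sinkhorn solver with epsilon
annealing: for squared-Euclidean cost the regularization is
`eps = blur^2`, lowered geometrically by `scaling^2` per level from the
squared diameter of the joint cloud down to the target, warm-starting the
dual potentials at each level. Each level iterates until the L1
row-marginal residual of the implied plan falls below `tol` (default 1e-6)
or `max_iter` (default 500) sweeps; a warning is emitted if the coldest
level stalls, which can happen near degenerate optima at very cold
epsilon. Plans returned to users are projected onto the transport polytope
(row/column scaling plus a rank-one correction), so their marginals are
exact; at `blur = 1e-3` the resulting cost agrees with the exact
linear-programming solution (the in-package oracle, for instances up to
64x64) to well under 1%. The divergence is debiased,
`S(a, b) = OT_eps(a, b) - OT_eps(a, a)/2 - OT_eps(b, b)/2`, and its
gradient with respect to the source points follows from the envelope
theorem applied to the converged plans. Inside training loops a looser
budget (`tol = 1e-2`, `max_iter = 50` per level) is used, which tracks the
fully converged divergence and gradient closely at a fraction of the cost.

## Growth estimation

Expected descendants of a cell over `dt_real` follow a birth–death model,
`n = exp(dt_real * (b - d))`. Birth and death rates come from logistic
maps of per-cell scores: the score is the mean z-score over a
cell-cycle (birth) or apoptosis (death) gene set, smoothed 5 times over
the 20 nearest neighbors in PCA space via
`s_i <- beta s_i + (1 - beta) mean(s_neighbors)` with `beta = 0.1`
(the neighbor graph is fixed; ties break by cell index; the cell itself is
excluded). Rates are `L0 + L / (1 + exp(-k s))` with `L0 = 0.3`,
`L = 1.2` per unit real time, bounding the net growth rate in (-1.2, 1.2);
the steepness is calibrated so the logistic term at the most extreme
observed score equals 0.001 of its range, `k = ln(1000)/|s_min|`,
separately for birth and death. With clone barcodes, the empirical
alternative counts cells sharing the barcode at the two times, with a
pseudocount of 1 in numerator and denominator so dropout in either
direction stays finite and positive; barcode-less cells get `n = 1`.

## Fate prediction and perturbations

Fate bias of a progenitor: simulate `n_traj = 2000` independent
trajectories from copies of its state to the final time, classify terminal
states by 20-nearest-neighbor majority vote over reference cell types
(exact neighbor search is the reference backend; vote ties break by
lexicographic label order), and compute
`(count_A + 1) / (count_A + count_B + 2)` — exactly 0.5 when neither
target fate is reached. Predictions ensemble by the arithmetic mean over
the last five training checkpoints. Scoring uses Pearson correlation
against barcode-derived truth and the AUROC of calling bias > 0.5.

Perturbations set target genes' z-scored expression to a chosen value
(negative: knockdown; positive: overexpression; the convention is
set-to-z, not add-z) and re-project through the fitted PCA, so the state
shift is exactly `sum_g (z - v_g) * loadings[g]`. Screens simulate paired
perturbed/unperturbed populations (default 200 cells x 10 repetitions,
sampled from the chosen stage weighted by growth estimates) with shared
noise streams, so a no-op edit yields literally zero difference and
differences isolate the perturbation. Significance: Welch's two-sided
t-test for independent designs or a paired two-sided t-test for screens,
across repetitions of the target-fate fraction; fold-changes are
`log2(mean perturbed / mean unperturbed)` with fractions floored at
`1/(n_cells * n_reps)`; multiple testing by Benjamini–Hochberg within each
target fate, hits requiring `q < 0.01` and `log2FC > 0.5`.

## Synthetic benchmarks

The generator simulates the exact Euler–Maruyama chain of a known
landscape at a fine step (0.02 days) while branching: each cell divides
per step with probability `birth_rate * dt_fine`, children inheriting the
clone barcode, so clone counts are genuinely emergent rather than
painted on. The default study takes snapshots at days 0, 1 and 2 of up to
500 cells each from a 2-D double well `Psi = (x1^2 - 1)^2 / 4 + x2^2 / 2`
with `sigma = 0.1`, progenitors starting near the saddle (spread 0.15).
The right basin proliferates so that expected descendants over the full
window are 3x the left basin's. Expression is a linear read-out into 30
genes (one third loading positively on the fate axis, one third
negatively, one third on the orthogonal axis, plus small random loadings
and Gaussian noise of sd 0.1); toy "cycle"/"apoptosis" gene sets are drawn
from the positive/negative blocks so signature scores genuinely correlate
with the planted growth, and one designated fate-axis gene gives
perturbations a predictable direction. Terminal cells are labeled by
basin. Two variants serve specific studies: `init_sd = 0.65` produces
fate-biased progenitors (commitment largely set at day 0), and
`init_mode = "bimodal"` starts two committed subpopulations.

What the fixtures do *not* emulate: count noise (dropout, library size —
expression is Gaussian around a linear map), unbalanced or partial
timepoint sampling, batch effects, or more than one bifurcation. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not robustness to
real-data artifacts.

## Validation experiments (desk scale)

`driftscape.benchmarks` fixes the protocols; the acceptance tests assert
on their outputs.

* **Pseudocount rule** — 2000 trajectories of a progenitor classified
  against basin labels only: zero counts for both queried fates, bias
  exactly 0.5.
* **Gradient field** — drift vs central finite differences (h = 1e-3) at
  100 random probes of a random 5-D potential: max relative error < 1e-4.
* **Stationary statistics** — the quadratic well simulated 2000 steps with
  5000 cells reproduces the Ornstein–Uhlenbeck stationary variance
  `sigma^2` within 3 standard errors. This check runs at `dt = 0.01`: the
  Euler chain's exact stationary variance is `sigma^2 / (1 - dt/2)`, so at
  the default `dt = 0.1` the +5% discretization bias would be comparable
  to the Monte-Carlo error and the comparison would test the bias, not the
  simulator.
* **Transport oracle** — 20 random weighted instances (m, M <= 8): Sinkhorn
  cost at blur 1e-3 within 1% of the exact LP.
* **Landscape recovery** — 3 models (seeds) trained on the default bistable
  study for 300 epochs recover the true drift with mean cosine similarity
  > 0.7 on a 20x20 grid restricted to within 0.2 of the data.
* **Held-out recovery** — trained on days 0 and 2 only, the simulated
  day-1 population is closer to the held-out snapshot than OT-midpoint
  interpolation in >= 2 of 3 seeds. Checkpoints every 25 epochs with
  argmin-training-distance selection; distances average two evaluation
  repetitions of 500 resampled cells, because single-shot margins sit near
  the Sinkhorn sampling noise floor.
* **Proliferation ablation** — on the fate-biased-progenitor variant, the
  proliferation-aware pipeline (descendant-weighted marginals in training;
  terminal composition predicted with accumulated lineage mass
  `exp(integral g dt)` per trajectory) allocates a larger mean terminal
  fraction to the 3x branch than the proliferation-blind pipeline over 3
  seeds. The committed variant is used because it pins fate at the first
  snapshot: a proliferation-blind model can otherwise partially absorb the
  branch expansion into spurious cross-barrier drift, and at convergence
  both pipelines estimate the same observed composition, so the margin of
  this comparison is small by nature.
* **Perturbation dose response** — on standardized PCA coordinates of the
  fixture (basins mapped to +/-1 so the analytic double well provides the
  dynamics), overexpressing the fate-axis gene across the ladder
  (-2.5, -1, -0.5, 2, 5, 10) with shared noise gives a non-decreasing
  target-basin fraction, and per-cell no-op edits give exactly zero paired
  differences.
* **Screen statistics** — Welch/paired t-statistics and BH q-values match
  hand-computed formulas on toy tables; all-null screens yield zero hits.

## Numerical conventions and edge cases

* Zero-variance genes scale to 0 rather than erroring.
* Variable-gene ranking breaks variance ties lexicographically; requesting
  all genes returns them in original column order.
* PCA components beyond the rank bound are dropped with a warning.
* `real_time_to_steps` rounds to the nearest integer step count and warns
  when the interval is not an integer multiple of `dt`.
* Simulation raises on the first non-finite state, naming the step.
* Weight initialization is N(0, 1/fan_in) from a fixed seed; every
  stochastic routine takes an explicit seed, and the CLI derives per-stage
  seeds by hashing the stage name with the global seed.
* With a zero learning rate the optimizer is a frozen no-op (useful for
  regression tests); `tau = 0` removes the regularizer term entirely.

## Limitations

Pure-numpy training is practical up to a few thousand cells and a few
hundred epochs; full-scale runs (10^5 cells, 50 PCs, 2500 epochs) want GPU
acceleration and are out of scope here. The potential is time-invariant,
so genuinely non-autonomous dynamics are fit only in a time-averaged
sense; noise is isotropic; and the final-snapshot steady-state assumption
biases the landscape when the last timepoint is far from equilibrium.
Identifiability of the drift away from the data support is not guaranteed
— recovery is measured only where cells were observed.
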