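import numpy as np
import pytest

import warnings

from driftscape import (MLPPotential, QuadraticPotential, SnapshotDataset,
                        TrainingConfig, evaluate_heldout, objective, pretrain,
                        simulate, train)

warnings.filterwarnings("ignore", message="Sinkhorn stopped")


def _zero_drift_model(k, c=0.0, sigma=1e-9):
    """MLP rigged to a constant potential c (zero weights): drift is zero."""
    m = MLPPotential(k=k, hidden=(4, 4), sigma=sigma, seed=0)
    m.params = [np.zeros_like(p) for p in m.params]
    m.params[-1][:] = c  # zero output weights: Psi(x) = output bias = c
    return m


class TestObjective:
    def test_perfect_fit_floor(self, rng):
        """Zero drift, negligible noise, identical snapshots: loss ~ 0."""
        cloud = rng.normal(size=(30, 2))
        data = SnapshotDataset(times=[0.0, 0.1], states=[cloud, cloud.copy()])
        model = _zero_drift_model(2, c=0.0)
        model.tau = 0.0
        cfg = TrainingConfig(batch_frac=1.0, seed=0)
        loss = objective(model, data, cfg, np.random.default_rng(0))
        assert abs(loss.value) < 1e-4

    def test_shifted_cloud_transport_law(self):
        """Point-mass pair shifted by v costs ~ ||v||^2 (tau = 0)."""
        v = np.array([0.5, -0.2])
        src = np.zeros((2, 2))  # two coincident cells: still a point mass
        tgt = np.tile(v, (2, 1))
        data = SnapshotDataset(times=[0.0, 0.1], states=[src, tgt])
        model = _zero_drift_model(2)
        model.tau = 0.0
        cfg = TrainingConfig(batch_frac=1.0, seed=0)
        loss = objective(model, data, cfg, np.random.default_rng(0))
        assert loss.value == pytest.approx(float(v @ v), rel=0.02)

    def test_regularizer_alone(self, rng):
        """With identical clouds the loss reduces to tau * m * c / sigma^2."""
        cloud = rng.normal(size=(20, 2))
        data = SnapshotDataset(times=[0.0, 0.1], states=[cloud, cloud.copy()])
        c = 1.7
        model = _zero_drift_model(2, c=c)
        model.tau = 1e-3
        cfg = TrainingConfig(batch_frac=1.0, seed=0)
        loss = objective(model, data, cfg, np.random.default_rng(0))
        expected = 1e-3 * 20 * c / model.sigma**2
        assert loss.value == pytest.approx(expected, rel=1e-3)

    def test_tau_term_linear_in_tau(self, rng):
        cloud = rng.normal(size=(20, 2))
        data = SnapshotDataset(times=[0.0, 0.1], states=[cloud, cloud.copy()])
        vals = []
        for tau in (1e-4, 2e-4):
            model = _zero_drift_model(2, c=1.0)
            model.tau = tau
            loss = objective(model, data, TrainingConfig(batch_frac=1.0, seed=0),
                             np.random.default_rng(0))
            vals.append(loss.value)
        assert vals[1] == pytest.approx(2 * vals[0], rel=1e-3)

    def test_single_snapshot_rejected(self, rng):
        data = SnapshotDataset(times=[0.0], states=[rng.normal(size=(5, 2))])
        with pytest.raises(ValueError):
            objective(MLPPotential(k=2, hidden=(4, 4), seed=0), data,
                      TrainingConfig(seed=0), np.random.default_rng(0))


class TestPretrain:
    def test_zero_steps_noop(self, rng):
        m = MLPPotential(k=2, hidden=(8, 8), seed=1)
        before = m.copy_params()
        pretrain(m, rng.normal(size=(50, 2)), steps=0)
        for a, b in zip(before, m.params):
            np.testing.assert_array_equal(a, b)

    def test_gaussian_gap_becomes_positive(self, rng):
        """After pretraining, data sits lower on the potential than background."""
        data = rng.normal(size=(300, 2)) * 0.3
        m = MLPPotential(k=2, hidden=(16, 16), seed=2)
        pretrain(m, data, steps=1000, lr=1e-2, seed=0)
        background = rng.uniform(-1.5, 1.5, size=(500, 2))
        gap = m.potential(background).mean() - m.potential(data).mean()
        assert gap > 0

    def test_deterministic_given_seed(self, rng):
        data = rng.normal(size=(40, 2))
        m1 = MLPPotential(k=2, hidden=(8, 8), seed=3)
        m2 = MLPPotential(k=2, hidden=(8, 8), seed=3)
        pretrain(m1, data, steps=20, lr=1e-4, seed=5)
        pretrain(m2, data, steps=20, lr=1e-4, seed=5)
        for a, b in zip(m1.params, m2.params):
            np.testing.assert_array_equal(a, b)

    def test_empty_snapshot_rejected(self):
        with pytest.raises(ValueError):
            pretrain(MLPPotential(k=2, seed=0), np.zeros((0, 2)), steps=1)


class TestTrain:
    @pytest.fixture(scope="class")
    def ou_data(self):
        """Snapshots of a contracting quadratic-well population."""
        rng = np.random.default_rng(10)
        model = QuadraticPotential(k=2, sigma=0.1, dt=0.1)
        x0 = rng.normal(size=(150, 2)) * 1.2
        traj = simulate(model, x0, 10, seed=11)
        return SnapshotDataset(times=[0.0, 1.0], states=[x0, traj.terminal])

    def test_loss_decreases_on_quadratic_fixture(self, ou_data):
        model = MLPPotential(k=2, hidden=(16, 16), seed=4)
        cfg = TrainingConfig(epochs=200, seed=4, eval_every=200, pretrain_steps=20)
        state = train(model, ou_data, cfg)
        early = np.mean(state.losses[:20])
        late = np.mean(state.losses[-20:])
        assert late < 0.5 * early

    def test_zero_learning_rate_freezes_parameters(self, ou_data):
        model = MLPPotential(k=2, hidden=(8, 8), sigma=0.0, tau=0.0, seed=5)
        before = model.copy_params()
        cfg = TrainingConfig(epochs=10, lr=0.0, batch_frac=1.0, seed=5,
                             eval_every=10, pretrain_steps=0)
        state = train(model, ou_data, cfg)
        for a, b in zip(before, model.params):
            np.testing.assert_array_equal(a, b)
        assert np.std(state.losses) < 1e-6 * max(1.0, abs(state.losses[0])) + 1e-9

    def test_training_is_reproducible(self, ou_data):
        runs = []
        for _ in range(2):
            model = MLPPotential(k=2, hidden=(8, 8), seed=6)
            cfg = TrainingConfig(epochs=15, seed=6, eval_every=5, pretrain_steps=5)
            runs.append((train(model, ou_data, cfg), model.copy_params()))
        np.testing.assert_array_equal(runs[0][0].losses, runs[1][0].losses)
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_checkpoints_reloadable(self, ou_data, tmp_path):
        model = MLPPotential(k=2, hidden=(8, 8), seed=7)
        cfg = TrainingConfig(epochs=10, seed=7, eval_every=5, pretrain_steps=0)
        state = train(model, ou_data, cfg, checkpoint_dir=str(tmp_path))
        assert [e for e, _ in state.checkpoints] == [5, 10]
        reloaded = MLPPotential.load(tmp_path / "checkpoint_epoch00010.npz")
        for a, b in zip(model.params, reloaded.params):
            np.testing.assert_array_equal(a, b)

    def test_lr_schedule_decays(self, ou_data):
        model = MLPPotential(k=2, hidden=(8, 8), seed=8)
        cfg = TrainingConfig(epochs=250, seed=8, eval_every=250, pretrain_steps=0)
        state = train(model, ou_data, cfg)
        assert state.lr_trace[99] == pytest.approx(0.01 * 0.9)
        assert state.lr_trace[199] == pytest.approx(0.01 * 0.81)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(batch_frac=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(lr=-1.0)


class TestEvaluateHeldout:
    def test_argmin_checkpoint_selection(self, rng):
        """The reported testing distance comes from the checkpoint with the
        lowest training distance."""
        cloud0 = rng.normal(size=(60, 2))
        model_true = QuadraticPotential(k=2, sigma=0.1, dt=0.1)
        mid = simulate(model_true, cloud0, 5, seed=1).terminal
        last = simulate(model_true, cloud0, 10, seed=1).terminal
        data = SnapshotDataset(times=[0.0, 0.5, 1.0], states=[cloud0, mid, last])

        good = MLPPotential(k=2, hidden=(8, 8), seed=1)
        # make a deliberately bad checkpoint by exploding the weights
        bad_params = [p * 50.0 for p in good.params]
        res = evaluate_heldout(good, data, 0.5, n_sim=200, seed=2,
                               checkpoints=[("bad", bad_params),
                                            ("good", good.copy_params())],
                               tol=1e-2, max_iter=20)
        distances = {r["epoch"]: r["train_distance"] for r in res["records"]}
        assert res["selected"]["epoch"] == min(distances, key=distances.get)

    def test_heldout_time_must_be_interior(self, rng):
        states = [rng.normal(size=(20, 2)) for _ in range(3)]
        data = SnapshotDataset(times=[0.0, 1.0, 2.0], states=states)
        m = MLPPotential(k=2, hidden=(4, 4), seed=0)
        with pytest.raises(ValueError):
            evaluate_heldout(m, data, 2.0, n_sim=10, seed=0)
        with pytest.raises(ValueError):
            evaluate_heldout(m, data, 0.7, n_sim=10, seed=0)
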