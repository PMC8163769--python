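import numpy as np
import pandas as pd
import pytest

from driftscape import (DEFAULT_Z_LADDER, DoubleWellPotential, PerturbationSpec,
                        apply_perturbation, call_hits, fit_classifier, fit_pca,
                        perturbation_stats, project, run_perturbation,
                        temporal_perturbation)


@pytest.fixture(scope="module")
def linear_system():
    """Scaled-expression pool with a known linear gene->state map.

    10 genes load onto 2 latent dimensions; genes 'g0' and 'g5' encode the
    fate axis redundantly (first PC direction up to sign) and 'g1' the
    orthogonal axis.
    """
    rng = np.random.default_rng(42)
    loadings = rng.normal(0, 0.05, size=(10, 2))
    loadings[0] = [0.6, 0.0]
    loadings[5] = [0.8, 0.0]
    loadings[1] = [0.0, 1.0]
    latent = rng.normal(size=(300, 2)) * 0.6
    scaled = latent @ loadings.T + rng.normal(0, 0.01, size=(300, 10))
    genes = [f"g{i}" for i in range(10)]
    pca = fit_pca(scaled, 2)
    return scaled, genes, pca


class TestApplyPerturbation:
    def test_noop_edit_leaves_state(self, linear_system):
        scaled, genes, pca = linear_system
        cell = scaled[:1].copy()
        spec = PerturbationSpec(genes=["g0"], z_value=float(cell[0, 0]))
        np.testing.assert_allclose(apply_perturbation(cell, genes, spec, pca),
                                   project(cell, pca), atol=1e-12)

    def test_analytic_shift_identity(self, linear_system):
        scaled, genes, pca = linear_system
        cell = scaled[:5].copy()
        z = 3.0
        spec = PerturbationSpec(genes=["g2"], z_value=z)
        shifted = apply_perturbation(cell, genes, spec, pca)
        expected = project(cell, pca) + np.outer(z - cell[:, 2], pca.loadings[2])
        np.testing.assert_allclose(shifted, expected, atol=1e-10)

    def test_ladder_monotone_displacement(self, linear_system):
        scaled, genes, pca = linear_system
        cell = scaled[:1].copy()
        base = project(cell, pca)
        direction = pca.loadings[0]
        projections = []
        for z in DEFAULT_Z_LADDER:
            spec = PerturbationSpec(genes=["g0"], z_value=z)
            moved = apply_perturbation(cell, genes, spec, pca)
            projections.append(((moved - base) @ direction).item())
        assert np.all(np.diff(projections) > 0)

    def test_unknown_gene(self, linear_system):
        scaled, genes, pca = linear_system
        with pytest.raises(KeyError):
            apply_perturbation(scaled[:1], genes,
                               PerturbationSpec(genes=["nope"], z_value=1.0), pca)

    def test_multi_gene_edit(self, linear_system):
        scaled, genes, pca = linear_system
        cell = scaled[:1].copy()
        spec = PerturbationSpec(genes=["g0", "g1"], z_value=2.0)
        out = apply_perturbation(cell, genes, spec, pca)
        expected = project(cell, pca) \
            + (2.0 - cell[0, 0]) * pca.loadings[0] \
            + (2.0 - cell[0, 1]) * pca.loadings[1]
        np.testing.assert_allclose(out, expected, atol=1e-10)


@pytest.fixture(scope="module")
def bistable_screen(linear_system):
    scaled, genes, pca = linear_system
    rng = np.random.default_rng(1)
    ref = np.vstack([rng.normal(size=(100, 2)) * 0.2 + [-1, 0],
                     rng.normal(size=(100, 2)) * 0.2 + [1, 0]])
    # map reference wells through the same PCA orientation as the pool
    ref_pca = np.sign(pca.loadings[0, 0]) * ref  # align fate axis sign
    labels = np.array(["left"] * 100 + ["right"] * 100)
    clf = fit_classifier(ref_pca, labels, k=10)
    model = DoubleWellPotential(k=2, a=1.0, sigma=0.1, dt=0.1)
    return scaled, genes, pca, clf, model


class TestRunPerturbation:
    def test_paired_noop_gives_identical_fractions(self, bistable_screen):
        scaled, genes, pca, clf, model = bistable_screen
        # set the gene to a constant the cells already carry: exact no-op
        pool = scaled.copy()
        pool[:, 3] = 0.7
        spec = PerturbationSpec(genes=["g3"], z_value=0.7, n_cells=40, n_reps=3)
        result = run_perturbation(model, spec, pool, genes, pca, clf, n_steps=10)
        unp = result[result["arm"] == "unperturbed"].sort_values("rep")
        per = result[result["arm"] == "perturbed"].sort_values("rep")
        for lab in ("left", "right"):
            np.testing.assert_array_equal(unp[lab].to_numpy(), per[lab].to_numpy())

    def test_dose_monotone_on_fate_axis(self, bistable_screen):
        """Overexpressing the fate-axis gene pushes cells into that basin."""
        scaled, genes, pca, clf, model = bistable_screen
        target = "right" if pca.loadings[0, 0] > 0 else "left"
        fractions = []
        # lower half of the dose ladder: stays within the Euler-stable
        # region of the cubic well (the full ladder is exercised in the
        # acceptance suite on standardized states)
        for z in (-2.5, -1.0, -0.5, 2.0):
            spec = PerturbationSpec(genes=["g0"], z_value=z, n_cells=100,
                                    n_reps=2, seed=9)
            result = run_perturbation(model, spec, scaled, genes, pca, clf,
                                      n_steps=20)
            fractions.append(result[result["arm"] == "perturbed"][target].mean())
        assert np.all(np.diff(fractions) >= 0)
        assert fractions[-1] > fractions[0]

    def test_control_gene_produces_no_shift(self, bistable_screen):
        """A gene with ~zero loading on the fate axis leaves fates unchanged."""
        scaled, genes, pca, clf, model = bistable_screen
        target = "right" if pca.loadings[0, 0] > 0 else "left"
        spec = PerturbationSpec(genes=["g7"], z_value=5.0, n_cells=100,
                                n_reps=10, seed=2)
        result = run_perturbation(model, spec, scaled, genes, pca, clf, n_steps=20)
        stats = perturbation_stats(result, target, mode="paired", n_cells=100)
        assert abs(stats["log2fc"]) < 0.1

    def test_empty_pool_rejected(self, bistable_screen):
        scaled, genes, pca, clf, model = bistable_screen
        with pytest.raises(ValueError):
            run_perturbation(model, PerturbationSpec(genes=["g0"], z_value=1.0),
                             np.zeros((0, 10)), genes, pca, clf, n_steps=5)


class TestPerturbationStats:
    def _frame(self, unp, per):
        rows = []
        for i, (u, p) in enumerate(zip(unp, per)):
            rows.append({"rep": i, "arm": "unperturbed", "fate": u})
            rows.append({"rep": i, "arm": "perturbed", "fate": p})
        return pd.DataFrame(rows)

    def test_null_case(self):
        frac = [0.5, 0.6, 0.4, 0.5]
        out = perturbation_stats(self._frame(frac, frac), "fate", mode="paired")
        assert out["p_value"] == 1.0
        assert out["log2fc"] == 0.0

    def test_exact_doubling(self):
        unp = [0.1, 0.2, 0.15, 0.25]
        per = [2 * u for u in unp]
        out = perturbation_stats(self._frame(unp, per), "fate", mode="independent")
        assert out["log2fc"] == pytest.approx(1.0)

    def test_welch_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        unp = rng.random(10)
        per = rng.random(10) + 0.2
        out = perturbation_stats(self._frame(unp, per), "fate", mode="independent")
        u, p = np.asarray(unp), np.asarray(per)
        se = np.sqrt(p.var(ddof=1) / 10 + u.var(ddof=1) / 10)
        assert out["t_stat"] == pytest.approx((p.mean() - u.mean()) / se)

    def test_paired_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        unp = rng.random(10)
        per = np.asarray(unp) + rng.normal(0.1, 0.05, 10)
        out = perturbation_stats(self._frame(unp, list(per)), "fate", mode="paired")
        d = per - np.asarray(unp)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert out["t_stat"] == pytest.approx(t)

    def test_zero_fraction_floor(self):
        out = perturbation_stats(self._frame([0.0, 0.0, 0.0], [0.1, 0.2, 0.1]),
                                 "fate", mode="paired", n_cells=200)
        assert np.isfinite(out["log2fc"])
        floor = 1 / (200 * 3)
        assert out["log2fc"] == pytest.approx(np.log2(np.mean([0.1, 0.2, 0.1]) / floor))

    def test_too_few_reps(self):
        with pytest.raises(ValueError):
            perturbation_stats(self._frame([0.5], [0.6]), "fate")


class TestCallHits:
    def test_all_null_screen_zero_hits(self):
        screen = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                               "target_fate": "beta",
                               "p_value": 1.0, "log2fc": 0.0})
        assert call_hits(screen)["hit"].sum() == 0

    def test_single_strong_hit_among_nulls(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([[1e-9], rng.uniform(0.2, 1.0, 200)])
        lfc = np.concatenate([[2.0], np.zeros(200)])
        screen = pd.DataFrame({"gene": [f"g{i}" for i in range(201)],
                               "target_fate": "beta", "p_value": p, "log2fc": lfc})
        out = call_hits(screen)
        assert bool(out.loc[0, "hit"])
        # BH arithmetic: smallest p among 201 tests
        assert out.loc[0, "q_value"] == pytest.approx(min(1e-9 * 201, 1.0))
        assert out["hit"].sum() == 1

    def test_conjunction_rule(self):
        screen = pd.DataFrame({"gene": ["a"], "target_fate": "beta",
                               "p_value": [1e-9], "log2fc": [0.2]})
        assert not call_hits(screen)["hit"].iloc[0]

    def test_invalid_p_values(self):
        screen = pd.DataFrame({"gene": ["a"], "target_fate": "b",
                               "p_value": [1.5], "log2fc": [0.0]})
        with pytest.raises(ValueError):
            call_hits(screen)


class TestTemporalPerturbation:
    def test_noop_everywhere_zero(self, bistable_screen):
        scaled, genes, pca, clf, model = bistable_screen
        pool = scaled.copy()
        pool[:, 4] = -0.3
        spec = PerturbationSpec(genes=["g4"], z_value=-0.3, n_cells=30, n_reps=2)
        out = temporal_perturbation(model, spec, {0.0: pool, 1.0: pool}, genes,
                                    pca, clf, t_final=2.0, target_fate="right")
        np.testing.assert_array_equal(out["mean_difference"].to_numpy(), 0.0)

    def test_step_bookkeeping(self, bistable_screen):
        scaled, genes, pca, clf, model = bistable_screen
        spec = PerturbationSpec(genes=["g0"], z_value=1.0, n_cells=10, n_reps=2)
        out = temporal_perturbation(model, spec, {0.0: scaled, 1.0: scaled},
                                    genes, pca, clf, t_final=2.0,
                                    target_fate="right")
        assert list(out["n_steps"]) == [20, 10]

    def test_effect_fades_after_commitment(self, bistable_screen):
        """Perturbing after cells have settled into basins changes little."""
        scaled, genes, pca, clf, model = bistable_screen
        target = "right" if pca.loadings[0, 0] > 0 else "left"
        # late pool: commitment redundantly encoded across g0 AND g5, so a
        # single-gene edit cannot move a committed cell across the barrier
        s0, s5 = np.sign(pca.loadings[0, 0]), np.sign(pca.loadings[5, 0])
        base = scaled[:200].copy()
        base[:, 0] = -1.5 * s0
        base[:, 5] = -1.5 * s5
        spec = PerturbationSpec(genes=["g0"], z_value=1.2 * s0, n_cells=60,
                                n_reps=3, seed=8)
        out = temporal_perturbation(model, spec,
                                    {0.0: scaled, 1.5: base}, genes, pca, clf,
                                    t_final=2.0, target_fate=target)
        early = out.loc[out["t_init"] == 0.0, "mean_difference"].iloc[0]
        late = out.loc[out["t_init"] == 1.5, "mean_difference"].iloc[0]
        assert early > late
        assert late < 0.15

    def test_init_after_final_rejected(self, bistable_screen):
        scaled, genes, pca, clf, model = bistable_screen
        spec = PerturbationSpec(genes=["g0"], z_value=1.0)
        with pytest.raises(ValueError):
            temporal_perturbation(model, spec, {2.0: scaled}, genes, pca, clf,
                                  t_final=2.0, target_fate="right")
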