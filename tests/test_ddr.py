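"""Stage classifier: grid, folds, MLP training schedule, metrics and
baseline harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from methrisk import _nn, ddr
from methrisk.data_io import BetaMatrix, CohortTable
from methrisk.synthdata import SimulationSpec, simulate_cohort


@pytest.fixture(scope="module")
def stage_cohort():
    """Strong stage signal, small: 160 samples x 20 marker sites."""
    spec = SimulationSpec(n_samples=160, n_cpgs=60, n_age_sites=5,
                          n_stage_sites=20, stage_delta=1.5, noise_sd=0.2,
                          seed=31, n_genes=20, planted_module_size=5)
    beta, cohort, truth = simulate_cohort(spec)
    return beta.subset_cpgs(truth.stage_site_ids), cohort


class TestGridAndPlan:
    def test_full_grid_size(self):
        assert len(ddr.DdrGrid().combos()) == 3 * 3 * 2 * 1 * 3 * 2 * 3

    def test_empty_option_list_rejected(self):
        with pytest.raises(ValueError):
            ddr.DdrGrid(neurons=())

    def test_balanced_ten_sample_plan(self):
        cohort = CohortTable(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(10)],
            "age": 60.0, "disease": "d", "stage": [0, 1] * 5}))
        plan = ddr.make_cv_plan(cohort, k_outer=5, k_inner=2, seed=0)
        for fold in plan.outer_folds:
            assert len(fold) == 2
            stages = {int(cohort.stages([s])[0]) for s in fold}
            assert stages == {0, 1}

    def test_partition_and_determinism(self, stage_cohort):
        _, cohort = stage_cohort
        p1 = ddr.make_cv_plan(cohort, 5, 3, seed=3)
        p2 = ddr.make_cv_plan(cohort, 5, 3, seed=3)
        assert p1.outer_folds == p2.outer_folds
        assert p1.inner_folds == p2.inner_folds
        all_ids = [s for f in p1.outer_folds for s in f]
        assert sorted(all_ids) == sorted(cohort.sample_ids)
        for f in range(5):
            inner_ids = [s for fold in p1.inner_folds[f] for s in fold]
            assert sorted(inner_ids) == sorted(p1.outer_train_ids(f))

    def test_small_class_rejected(self):
        cohort = CohortTable(pd.DataFrame({
            "sample_id": ["a", "b", "c"], "age": 50.0,
            "disease": "d", "stage": [0, 0, 1]}))
        with pytest.raises(ValueError, match="class"):
            ddr.make_cv_plan(cohort, k_outer=5)


class TestMlp:
    def test_separable_reaches_training_accuracy_one(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.repeat([0, 1], n // 2)
        x = np.clip(0.3 + 0.4 * y[None, :] + rng.normal(0, 0.02, (2, n)), 0, 1)
        beta = BetaMatrix(["c1", "c2"], [f"S{i}" for i in range(n)], x)
        model = ddr.train_mlp(ddr.DdrConfig(hidden_layers=2, neurons=16),
                              beta, y, ddr.DdrTrainFixed(seed=1))
        pred = (ddr.predict_stage_proba(model, beta) >= 0.5).astype(int)
        assert (pred == y).mean() == 1.0

    def test_plateau_decay_rule_applied_twice(self):
        opt = _nn.Adam(lr=0.001)
        sched = _nn.PlateauScheduler(opt, patience=30, factor=0.2, rel_tol=1e-4)
        sched.update(1.0)               # sets the best loss
        for _ in range(60):             # 60 stagnant epochs
            sched.update(1.0)
        assert opt.lr == pytest.approx(0.001 * 0.2 ** 2)

    def test_lr_decays_during_training_on_plateau(self, stage_cohort):
        beta, cohort = stage_cohort
        fixed = ddr.DdrTrainFixed(epochs=120, seed=2)
        model = ddr.train_mlp(ddr.DdrConfig(), beta,
                              cohort.stages().astype(int), fixed)
        assert len(model.lr_schedule) == 120
        assert model.lr_schedule[-1] <= model.lr_schedule[0]

    def test_identical_inputs_identical_probabilities(self, stage_cohort):
        beta, cohort = stage_cohort
        model = ddr.train_mlp(ddr.DdrConfig(hidden_layers=2, neurons=16,
                                            dropout=0.1), beta,
                              cohort.stages().astype(int),
                              ddr.DdrTrainFixed(epochs=20, seed=3))
        dup = BetaMatrix(list(beta.cpg_ids), ["A", "B"],
                         np.repeat(beta.values[:, :1], 2, axis=1))
        p = ddr.predict_stage_proba(model, dup)
        assert p[0] == p[1]

    def test_single_class_rejected(self, stage_cohort):
        beta, _ = stage_cohort
        with pytest.raises(ValueError, match="single class"):
            ddr.train_mlp(ddr.DdrConfig(), beta,
                          np.ones(beta.n_samples, dtype=int),
                          ddr.DdrTrainFixed())

    def test_training_deterministic(self, stage_cohort):
        beta, cohort = stage_cohort
        y = cohort.stages().astype(int)
        fixed = ddr.DdrTrainFixed(epochs=15, seed=4)
        m1 = ddr.train_mlp(ddr.DdrConfig(dropout=0.1), beta, y, fixed)
        m2 = ddr.train_mlp(ddr.DdrConfig(dropout=0.1), beta, y, fixed)
        assert m1.history == m2.history
        np.testing.assert_array_equal(ddr.predict_stage_proba(m1, beta),
                                      ddr.predict_stage_proba(m2, beta))


class TestEvaluate:
    def test_perfect_ranking(self):
        m = ddr.evaluate([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert m == {"auc": 1.0, "acc": 1.0, "precision": 1.0, "recall": 1.0}

    def test_three_of_four_pairs(self):
        m = ddr.evaluate([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert m["auc"] == pytest.approx(0.75)

    def test_all_tied_scores_auc_half(self):
        assert ddr.evaluate([0.5] * 6, [1, 0, 1, 0, 1, 0])["auc"] == 0.5

    def test_single_class_raises_with_acc_in_message(self):
        with pytest.raises(ValueError, match="ACC"):
            ddr.evaluate([0.6, 0.7], [1, 1])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_sklearn_rank_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = rng.integers(0, 2, n)
        if len(set(y.tolist())) < 2:
            y[0], y[1] = 0, 1
        s = rng.integers(0, 5, n) / 4.0   # coarse grid forces ties
        assert ddr.evaluate(s, y)["auc"] == pytest.approx(roc_auc_score(y, s))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 1, 30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a1 = ddr.evaluate(s, y)["auc"]
        a2 = ddr.evaluate(s ** 3, y)["auc"]
        assert a1 == pytest.approx(a2)


class TestCv:
    def test_run_cv_no_leakage_and_strong_signal(self, stage_cohort):
        beta, cohort = stage_cohort
        plan = ddr.make_cv_plan(cohort, 3, 3, seed=5)
        grid = ddr.DdrGrid(hidden_layers=(2,), neurons=(16,), dropout=(0.0,),
                           regularization=("l2",), activation=("selu",),
                           learning_rate=(0.001,))
        fixed = ddr.DdrTrainFixed(epochs=60, seed=5)
        report, details = ddr.run_cv(beta, cohort, grid, fixed, plan)
        assert report.table["auc"].iloc[0] >= 0.95
        for f, test_ids in enumerate(plan.outer_folds):
            inner_ids = {s for fold in plan.inner_folds[f] for s in fold}
            assert not (set(test_ids) & inner_ids)

    def test_run_cv_deterministic(self, stage_cohort):
        beta, cohort = stage_cohort
        plan = ddr.make_cv_plan(cohort, 3, 2, seed=6)
        grid = ddr.DdrGrid(hidden_layers=(2,), neurons=(16,), dropout=(0.0,),
                           regularization=("l2",), activation=("relu",),
                           learning_rate=(0.001,))
        fixed = ddr.DdrTrainFixed(epochs=25, seed=6)
        r1, _ = ddr.run_cv(beta, cohort, grid, fixed, plan)
        r2, _ = ddr.run_cv(beta, cohort, grid, fixed, plan)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_label_permutation_null_band(self, stage_cohort):
        beta, cohort = stage_cohort
        rng = np.random.default_rng(7)
        t = cohort.table.copy()
        t["stage"] = rng.permutation(t["stage"].to_numpy())
        null_cohort = CohortTable(t)
        plan = ddr.make_cv_plan(null_cohort, 3, 2, seed=7)
        grid = ddr.DdrGrid(hidden_layers=(2,), neurons=(16,), dropout=(0.0,),
                           regularization=("l2",), activation=("selu",),
                           learning_rate=(0.001,))
        report, _ = ddr.run_cv(beta, null_cohort, grid,
                               ddr.DdrTrainFixed(epochs=60, seed=7), plan)
        assert 0.35 <= report.table["auc"].iloc[0] <= 0.65


class TestBaselines:
    def test_logistic_regression_on_separable_cohort(self, stage_cohort):
        beta, cohort = stage_cohort
        plan = ddr.make_cv_plan(cohort, 3, 3, seed=8)
        report, details = ddr.run_baselines(beta, cohort, plan,
                                            ["logistic_regression"], seed=8)
        assert report.table["auc"].iloc[0] >= 0.9
        assert details["outer_folds"] == plan.outer_folds

    def test_report_row_per_model(self, stage_cohort):
        beta, cohort = stage_cohort
        plan = ddr.make_cv_plan(cohort, 3, 2, seed=9)
        models = ["knn", "naive_bayes"]
        report, _ = ddr.run_baselines(beta, cohort, plan, models, seed=9)
        assert list(report.table["model"]) == models

    def test_unknown_model_rejected(self, stage_cohort):
        beta, cohort = stage_cohort
        plan = ddr.make_cv_plan(cohort, 3, 2, seed=10)
        with pytest.raises(ValueError, match="unknown baseline"):
            ddr.run_baselines(beta, cohort, plan, ["perceptron"])
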