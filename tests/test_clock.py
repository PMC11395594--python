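"""Multi-scale convolutional clock: architecture, training, prediction,
and the subset-retrain comparison."""

import dataclasses

import numpy as np
import pytest

from methrisk import clock as ck
from methrisk.clock import ClockConfig, build_clock, mad, predict_age, train_clock
from methrisk.synthdata import SimulationSpec, simulate_cohort

from conftest import split_samples


class TestArchitecture:
    def test_concatenated_feature_length(self):
        cfg = ClockConfig(n_input_sites=30, kernel_sizes=(1, 8, 16, 32),
                          channels_per_scale=4)
        model = build_clock(cfg)
        x = np.random.default_rng(0).uniform(0, 1, (5, 30))
        _, cache = ck._forward(model.params, x, cfg, want_cache=True)
        assert cache["feats"].shape == (5, 16)   # 4 scales x 4 channels

    def test_same_seed_identical_initialization(self):
        cfg = ClockConfig(n_input_sites=20, seed=7)
        a, b = build_clock(cfg), build_clock(cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_single_kernel_degenerate_scale(self):
        cfg = ClockConfig(n_input_sites=10, kernel_sizes=(1,))
        model = build_clock(cfg)
        out = ck._forward(model.params, np.full((3, 10), 0.5), cfg)
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_kernel_larger_than_fc1_rejected(self):
        with pytest.raises(ValueError, match="fc1_width"):
            ClockConfig(n_input_sites=10, fc1_width=16, kernel_sizes=(32,))

    @pytest.mark.parametrize("kernels,channels,fc1", [
        ((1, 8, 16, 32), 4, 64), ((1, 4), 2, 16), ((3,), 8, 32)])
    def test_parameter_count_closed_form(self, kernels, channels, fc1):
        cfg = ClockConfig(n_input_sites=25, kernel_sizes=kernels,
                          channels_per_scale=channels, fc1_width=fc1)
        model = build_clock(cfg)
        assert sum(v.size for v in model.params.values()) == ck.parameter_count(cfg)

    def test_parameter_count_linear_in_channels_and_scales(self):
        base = ClockConfig(n_input_sites=25)
        c1 = ck.parameter_count(dataclasses.replace(base, channels_per_scale=1))
        c2 = ck.parameter_count(dataclasses.replace(base, channels_per_scale=2))
        c3 = ck.parameter_count(dataclasses.replace(base, channels_per_scale=3))
        assert c3 - c2 == c2 - c1


class TestMad:
    def test_identity_and_offset(self):
        assert mad([30, 40], [30, 40]) == 0.0
        assert mad(np.array([35, 45]), np.array([30, 40])) == 5.0

    def test_direct_arithmetic(self):
        assert mad([30, 40], [28, 44]) == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mad([1, 2], [1])


class TestTraining:
    def test_noiseless_heldout_mad_below_2_years(self, noiseless_cohort,
                                                 trained_noiseless_clock):
        _, beta, cohort, _ = noiseless_cohort
        model, _, test_ids = trained_noiseless_clock
        held = beta.subset_samples(test_ids)
        pred = predict_age(model, held)
        true = cohort.ages(test_ids)
        assert mad(pred, true) < 2.0
        assert np.corrcoef(pred, true)[0, 1] > 0.99

    def test_training_loss_decreases_smoothed(self, trained_noiseless_clock):
        h = np.array(trained_noiseless_clock[0].history)
        smoothed = np.convolve(h, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] < smoothed[0]
        # non-increasing over 10-epoch windows up to small jitter
        assert np.all(np.diff(smoothed[::10]) < 0.05)

    def test_shuffled_ages_no_better_than_mean(self, noiseless_cohort):
        _, beta, cohort, _ = noiseless_cohort
        ages = cohort.ages()
        rng = np.random.default_rng(0)
        tr, te = split_samples(beta, 1, 150)
        ages_of = dict(zip(beta.sample_ids, ages))
        tr_ages = np.array([ages_of[s] for s in tr])
        te_ages = np.array([ages_of[s] for s in te])
        cfg = ClockConfig(n_input_sites=beta.n_cpgs, seed=3, epochs=60)
        model = build_clock(cfg)
        train_clock(model, beta.subset_samples(tr), rng.permutation(tr_ages), cfg)
        null_mad = mad(predict_age(model, beta.subset_samples(te)), te_ages)
        mean_mad = mad(np.full_like(te_ages, tr_ages.mean()), te_ages)
        assert null_mad >= mean_mad * 0.9

    def test_missing_age_rejected(self, noiseless_cohort):
        _, beta, cohort, _ = noiseless_cohort
        ages = cohort.ages().copy()
        ages[0] = np.nan
        cfg = ClockConfig(n_input_sites=beta.n_cpgs)
        with pytest.raises(ValueError, match="age"):
            train_clock(build_clock(cfg), beta, ages, cfg)

    def test_age_scaling_sanity(self):
        """Retraining on c-scaled ages scales predictions by ~c."""
        spec = SimulationSpec(n_samples=120, n_cpgs=40, n_age_sites=15,
                              n_stage_sites=5, noise_sd=0.0, seed=8,
                              n_genes=10, planted_module_size=4)
        beta, cohort, _ = simulate_cohort(spec)
        ages = cohort.ages()
        cfg = ClockConfig(n_input_sites=40, seed=2, epochs=60)
        m1 = train_clock(build_clock(cfg), beta, ages, cfg)
        p1 = predict_age(m1, beta)
        m2 = train_clock(build_clock(cfg), beta, 2.0 * ages, cfg)
        p2 = predict_age(m2, beta)
        slope = np.polyfit(p1, p2, 1)[0]
        assert 1.6 <= slope <= 2.4


class TestPrediction:
    def test_deterministic_and_sample_order_invariant(self, noiseless_cohort,
                                                      trained_noiseless_clock):
        _, beta, _, _ = noiseless_cohort
        model = trained_noiseless_clock[0]
        p1 = predict_age(model, beta)
        p2 = predict_age(model, beta)
        np.testing.assert_array_equal(p1, p2)
        perm = np.random.default_rng(1).permutation(beta.n_samples)
        shuffled = beta.subset_samples([beta.sample_ids[i] for i in perm])
        p3 = predict_age(model, shuffled)
        np.testing.assert_allclose(p3, p1[perm], rtol=1e-12)

    def test_missing_cpg_listed(self, noiseless_cohort, trained_noiseless_clock):
        _, beta, _, _ = noiseless_cohort
        reduced = beta.subset_cpgs(beta.cpg_ids[:-1])
        with pytest.raises(ValueError, match=beta.cpg_ids[-1]):
            predict_age(trained_noiseless_clock[0], reduced)

    def test_extra_cpgs_are_reordered_away(self, noiseless_cohort,
                                           trained_noiseless_clock):
        _, beta, _, _ = noiseless_cohort
        model = trained_noiseless_clock[0]
        reversed_beta = beta.subset_cpgs(list(reversed(beta.cpg_ids)))
        np.testing.assert_allclose(predict_age(model, reversed_beta),
                                   predict_age(model, beta), rtol=1e-12)


class TestSubsetRetrain:
    def test_identity_subset_equal_mads(self):
        spec = SimulationSpec(n_samples=80, n_cpgs=30, n_age_sites=10,
                              n_stage_sites=5, noise_sd=0.1, seed=12,
                              n_genes=10, planted_module_size=4)
        beta, cohort, _ = simulate_cohort(spec)
        cfg = ClockConfig(n_input_sites=30, seed=4, epochs=30)
        rec = ck.compare_subset_retrain(beta, cohort.ages(), beta.cpg_ids,
                                        list(beta.cpg_ids), cfg, k_folds=3)
        assert rec["full_mad"] == rec["subset_mad"]
        assert len(rec["full_mad"]) == 3

    def test_subset_not_contained_rejected(self, noiseless_cohort):
        _, beta, cohort, _ = noiseless_cohort
        cfg = ClockConfig(n_input_sites=beta.n_cpgs)
        with pytest.raises(ValueError, match="subset"):
            ck.compare_subset_retrain(beta, cohort.ages(), beta.cpg_ids[:5],
                                      ["not_a_cpg"], cfg)

    def test_informative_subset_not_worse(self):
        """All informative sites inside the subset, complement pure noise:
        subset MAD must not exceed full MAD + 0.5 years (mean over folds)."""
        spec = SimulationSpec(n_samples=150, n_cpgs=300, n_age_sites=25,
                              n_stage_sites=5, noise_sd=0.2, seed=13,
                              n_genes=20, planted_module_size=5)
        beta, cohort, truth = simulate_cohort(spec)
        subset = truth.age_site_ids + truth.stage_site_ids
        cfg = ClockConfig(n_input_sites=300, seed=5, epochs=60)
        rec = ck.compare_subset_retrain(beta, cohort.ages(), beta.cpg_ids,
                                        subset, cfg, k_folds=3)
        assert rec["subset_mad_mean"] <= rec["full_mad_mean"] + 0.5


def test_full_training_determinism():
    spec = SimulationSpec(n_samples=60, n_cpgs=25, n_age_sites=8,
                          n_stage_sites=4, noise_sd=0.1, seed=14,
                          n_genes=10, planted_module_size=4)
    beta, cohort, _ = simulate_cohort(spec)
    cfg = ClockConfig(n_input_sites=25, seed=6, epochs=25)
    m1 = train_clock(build_clock(cfg), beta, cohort.ages(), cfg)
    m2 = train_clock(build_clock(cfg), beta, cohort.ages(), cfg)
    assert m1.history == m2.history
    np.testing.assert_array_equal(predict_age(m1, beta), predict_age(m2, beta))


def test_save_load_round_trip(tmp_path, noiseless_cohort, trained_noiseless_clock):
    _, beta, _, _ = noiseless_cohort
    model = trained_noiseless_clock[0]
    ck.save_clock(model, tmp_path)
    loaded = ck.load_clock(tmp_path)
    np.testing.assert_array_equal(predict_age(loaded, beta),
                                  predict_age(model, beta))
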