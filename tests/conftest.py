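"""Shared fixtures.  Expensive artifacts (trained clocks, full-scale
simulated cohorts) are session-scoped so the suite trains each model once."""

from __future__ import annotations

import numpy as np
import pytest

from methrisk import clock as ck
from methrisk.synthdata import SimulationSpec, simulate_all, simulate_cohort


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study at the reference conditions (400 x 2000)."""
    return simulate_all(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise cohort: 200 samples x 60 sites, 20 age-informative."""
    spec = SimulationSpec(n_samples=200, n_cpgs=60, n_age_sites=20,
                          n_stage_sites=5, noise_sd=0.0, n_genes=20,
                          planted_module_size=5, seed=11)
    beta, cohort, truth = simulate_cohort(spec)
    return spec, beta, cohort, truth


@pytest.fixture(scope="session")
def trained_noiseless_clock(noiseless_cohort):
    """Clock trained on 150 of the 200 noiseless samples; the held-out
    sample ids ride along for generalization checks."""
    spec, beta, cohort, truth = noiseless_cohort
    train_ids, test_ids = split_samples(beta, 99, 150)
    cfg = ck.ClockConfig(n_input_sites=beta.n_cpgs, seed=5)
    model = ck.build_clock(cfg)
    ck.train_clock(model, beta.subset_samples(train_ids),
                   cohort.ages(train_ids), cfg)
    return model, train_ids, test_ids


@pytest.fixture(scope="session")
def attribution_cohort():
    """Zero-noise cohort sized for attribution recovery: 50 informative
    sites among 500, 200 samples."""
    spec = SimulationSpec(n_samples=200, n_cpgs=500, n_age_sites=50,
                          n_stage_sites=10, noise_sd=0.0, n_genes=50,
                          planted_module_size=8, seed=21)
    beta, cohort, truth = simulate_cohort(spec)
    cfg = ck.ClockConfig(n_input_sites=500, seed=5)
    model = ck.build_clock(cfg)
    ck.train_clock(model, beta, cohort.ages(), cfg)
    return beta, cohort, truth, model


def split_samples(beta, rng_seed, n_first):
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(beta.n_samples)
    first = [beta.sample_ids[i] for i in perm[:n_first]]
    rest = [beta.sample_ids[i] for i in perm[n_first:]]
    return first, rest
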