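"""Shared fixtures: synthetic cohorts and trained fits reused across tests.

Training fixtures are session-scoped because fits are deterministic given
their seeds; sharing them keeps the suite fast.
"""

import numpy as np
import pytest

import losrange as lr


# ---------------------------------------------------------------------------
# regime A (homoscedastic, near-linear): used for calibration checks
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cohort_a():
    spec = lr.CohortSpec(n_patients=20_000, regime="A", seed=101, noise_sd_hours=15.0)
    table = lr.generate_cohort(spec)
    split = lr.split_train_test(table, 0.9, seed=101)
    return table.subset(split.train_idx), table.subset(split.test_idx)


@pytest.fixture(scope="session")
def regressor_a(cohort_a):
    train, test = cohort_a
    return lr.train_regressor(train, lr.NetConfig(seed=101), test=test)


# ---------------------------------------------------------------------------
# regime A with stronger noise (30 h): error-net and dist-net oracles
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cohort_a30():
    spec = lr.CohortSpec(n_patients=12_000, regime="A", seed=303, noise_sd_hours=30.0)
    table = lr.generate_cohort(spec)
    split = lr.split_train_test(table, 0.9, seed=303)
    return table.subset(split.train_idx), table.subset(split.test_idx)


@pytest.fixture(scope="session")
def regressor_a30(cohort_a30):
    train, test = cohort_a30
    return lr.train_regressor(train, lr.NetConfig(seed=303), test=test)


@pytest.fixture(scope="session")
def errornet_a30(cohort_a30, regressor_a30):
    train, _ = cohort_a30
    return lr.train_error_net(train, regressor_a30, lr.NetConfig(seed=303))


@pytest.fixture(scope="session")
def distnet3_a30(cohort_a30):
    train, _ = cohort_a30
    return lr.train_dist_net(train, lr.LossConfig("loss3"), lr.NetConfig(seed=303))


# ---------------------------------------------------------------------------
# regime C (many features, heteroscedastic): recovery and comparison
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cohort_c():
    spec = lr.CohortSpec(n_patients=20_000, regime="C", seed=202)
    table = lr.generate_cohort(spec)
    split = lr.split_train_test(table, 0.9, seed=202)
    return table.subset(split.train_idx), table.subset(split.test_idx)


@pytest.fixture(scope="session")
def regressor_c(cohort_c):
    train, test = cohort_c
    return lr.train_regressor(train, lr.NetConfig(seed=202), test=test)


@pytest.fixture(scope="session")
def errornet_c(cohort_c, regressor_c):
    train, _ = cohort_c
    return lr.train_error_net(train, regressor_c, lr.NetConfig(seed=202))


@pytest.fixture(scope="session")
def distnet3_c(cohort_c):
    train, _ = cohort_c
    return lr.train_dist_net(train, lr.LossConfig("loss3"), lr.NetConfig(seed=202))


# ---------------------------------------------------------------------------
# reduced cohort for adversarial training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def gan_bundle_c():
    table = lr.generate_cohort(lr.CohortSpec(n_patients=2_000, regime="C", seed=404))
    bundle = lr.train_wgan_gp(table, lr.GanConfig(seed=404))
    return table, bundle
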