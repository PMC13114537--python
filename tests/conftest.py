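import numpy as np
import pytest

import erstress as es

# Simulation-study conditions: the three-level cell with true shape 0.8,
# scales (0.01, 0.02, 0.03) and stress changes at 6 and 8 time units.
CELL = dict(alpha=0.8, betas=(0.01, 0.02, 0.03), change_times=(6, 8), n=100)
STUDY_SEED = 20260926


@pytest.fixture(scope="session")
def fish():
    return es.fish_data()


@pytest.fixture(scope="session")
def fish_fit(fish):
    return es.fit_order_restricted(fish)


@pytest.fixture(scope="session")
def easy_data():
    """Well-separated three-level sample where the restriction never binds."""
    params = es.CEMParams(0.8, (0.01, 0.05, 0.2))
    sched = es.StressSchedule((6, 8))
    times, _ = es.cem_sample(200, params, sched, 7)
    return es.make_dataset(times, sched)


@pytest.fixture(scope="session")
def binding_data():
    """Sample generated with decreasing scales, so the unrestricted ratio
    estimate exceeds 1 and the fit must bind beta_1 = beta_2."""
    rng = np.random.default_rng(11)
    sched = es.StressSchedule((2.0,))
    # inverse-transform draw from the *unordered* composed law
    betas = np.array([0.2, 0.02])
    alpha = 1.0
    c = np.array([0.0, np.sqrt(betas[0] / betas[1]) * 2.0])
    p1 = (1 - np.exp(-betas[0] * 2.0**2)) ** alpha
    u = rng.uniform(size=120)
    lev = (u > p1).astype(int)
    taus = np.array([0.0, 2.0])
    t = taus[lev] + np.sqrt(-np.log(1 - u ** (1 / alpha)) / betas[lev]) - c[lev]
    return es.make_dataset(t, sched)


@pytest.fixture(scope="session")
def mle_study():
    """Reduced-replication MLE study of the reference cell (500 replicates)."""
    cfg = es.StudyConfig(**CELL, replications=500, seed=STUDY_SEED, method="mle")
    return es.run_study(cfg)


@pytest.fixture(scope="session")
def bayes_study():
    """Reduced-replication Bayes study of the reference cell (200 replicates)."""
    cfg = es.StudyConfig(
        **CELL, replications=200, seed=STUDY_SEED + 1, method="bayes",
        interval="symmetric", n_draws=10_000,
    )
    return es.run_study(cfg)
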