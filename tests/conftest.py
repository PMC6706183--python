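import numpy as np
import pandas as pd
import pytest

from storksurv.simulate import SimConfig, simulate_cohort, simulate_daily


@pytest.fixture(scope="session")
def stream_cohort():
    """Small full-resolution cohort shared across stream-level tests.

    Sampling density is reduced relative to the tag defaults purely to
    keep the fixture quick; hazard and effect parameters are defaults.
    """
    cfg = SimConfig(n_individuals=6, seed=5, gps_interval_s=(600, 1200),
                    acc_gap_min=(45, 90))
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def daily_cohort():
    """Daily-resolution cohort (features, odba, fates, phenology,
    metadata, truth) for stage/model tests."""
    cfg = SimConfig(n_individuals=150, seed=9)
    return cfg, simulate_daily(cfg)


def random_survival_frame(rng, n=80, p=2, beta=None, censor_hi=25.0,
                          round_times=True):
    """Generic right-censored dataset with known log-hazard ratios."""
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    X = rng.normal(size=(n, p))
    t = rng.exponential(10.0 * np.exp(-X @ beta))
    c = rng.uniform(0, censor_hi, n)
    if round_times:
        t, c = np.ceil(t), np.ceil(c)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    df = pd.DataFrame({"time_days": np.maximum(time, 0.5), "event": event})
    for j in range(p):
        df[f"x{j}"] = X[:, j]
    return df
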