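"""Generator contracts: determinism, signatures, window compliance,
closed-form death fractions."""

import numpy as np
import pandas as pd
import pytest

from storksurv.io import write_acc, write_gps
from storksurv.simulate import (ConfigError, SimConfig, simulate_acc_burst,
                                simulate_cohort, simulate_daily)


class TestConfig:
    def test_negative_hazard_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(baseline_hazards={"postfledging": -0.1,
                                        "migration": 0, "winter": 0})

    def test_region_probs_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimConfig(region_probs={"Europe": 0.5, "NorthAfrica": 0.2,
                                    "SubSaharan": 0.2})

    def test_zero_individuals_gives_empty_streams(self):
        cohort = simulate_cohort(SimConfig(n_individuals=0))
        assert len(cohort.gps) == 0
        assert cohort.acc == {}


class TestAccBurst:
    def test_sample_count_is_rounded_product(self):
        b = simulate_acc_burst(0.0, 2.0, 20.0, False)
        assert len(b.samples) == 40
        assert np.all(b.samples == b.samples[0])
        assert len(simulate_acc_burst(1.0, 1.2, 10.54, True).samples) == 13
        b2 = simulate_acc_burst(1.0, 4.1, 33.33, False,
                                rng=np.random.default_rng(0))
        assert len(b2.samples) == 137
        assert np.all(b2.samples.var(axis=0) > 0)

    def test_post_death_constant(self):
        b = simulate_acc_burst(2.0, 2.0, 20.0, True)
        assert np.all(np.ptp(b.samples, axis=0) == 0)

    def test_bad_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_acc_burst(1.0, 0.0, 20.0, False)


def test_zero_hazard_zero_vanish_all_alive():
    cfg = SimConfig(n_individuals=20, seed=3, vanish_rate=0.0,
                    baseline_hazards={"postfledging": 0.0,
                                      "migration": 0.0, "winter": 0.0})
    *_, truth = simulate_daily(cfg)
    assert (truth["true_fate"] == "alive").all()


def test_byte_identical_reruns(tmp_path, stream_cohort):
    """Identical (config, seed) must reproduce identical CSV bytes."""
    cfg, cohort = stream_cohort
    again = simulate_cohort(cfg)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_gps(cohort.gps, p1)
    write_gps(again.gps, p2)
    assert p1.read_bytes() == p2.read_bytes()
    ind = sorted(cohort.acc)[0]
    write_acc({ind: cohort.acc[ind]}, p1)
    write_acc({ind: again.acc[ind]}, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_recording_window_respected(stream_cohort):
    """No fix or burst outside the 02:00-20:00 UTC duty cycle."""
    _, cohort = stream_cohort
    hours = cohort.gps["timestamp"].dt.hour
    assert ((hours >= 2) & (hours < 20)).all()
    for bursts in cohort.acc.values():
        for b in bursts:
            assert 2 <= b.start.hour < 20
            end = b.start + pd.Timedelta(seconds=b.duration_s)
            assert end.hour < 20


def test_post_death_signatures(stream_cohort):
    """After the true death day: flat bursts, fixes near death point."""
    from storksurv.tracks import haversine_km

    _, cohort = stream_cohort
    dead = cohort.truth[cohort.truth["true_fate"] == "dead"]
    checked = 0
    for row in dead.itertuples():
        dd = pd.Timestamp(row.true_death_date)
        bursts = [b for b in cohort.acc[row.individual_id]
                  if b.start >= dd + pd.Timedelta(days=1)]
        for b in bursts:
            assert np.all(np.ptp(b.samples, axis=0) == 0)
        fx = cohort.gps[(cohort.gps["individual_id"] == row.individual_id)
                        & (cohort.gps["timestamp"] >= dd)]
        if len(fx) > 1:
            ref_lat, ref_lon = fx["lat"].iloc[0], fx["lon"].iloc[0]
            d = haversine_km(fx["lat"].to_numpy(), fx["lon"].to_numpy(),
                             ref_lat, ref_lon) * 1000
            assert np.max(d) <= 100.0
        checked += 1
    if len(dead) == 0:
        pytest.skip("no deaths drawn in this fixture")


def test_vanished_have_no_posterior_records(stream_cohort):
    _, cohort = stream_cohort
    vanished = cohort.truth[cohort.truth["true_fate"] == "vanished"]
    for row in vanished.itertuples():
        vd = pd.Timestamp(row.true_vanish_date)
        fx = cohort.gps[cohort.gps["individual_id"] == row.individual_id]
        assert fx["timestamp"].max() < vd + pd.Timedelta(days=1)


def test_death_fraction_matches_closed_form():
    """Constant hazard, no covariate effects, fixed windows: the death
    fraction is binomial around 1 - exp(-lambda * L)."""
    lam = 0.01
    cfg = SimConfig(
        n_individuals=500, seed=77, vanish_rate=0.0,
        fledge_doy_mean_sd=(190, 0), depart_doy_mean_sd=(225, 0),
        beta_true={},
        baseline_hazards={"postfledging": lam, "migration": 0.0,
                          "winter": 0.0})
    *_, truth = simulate_daily(cfg)
    frac = (truth["true_fate"] == "dead").mean()
    length = 225 - 190  # fixed postfledging window, days
    p = 1 - np.exp(-lam * length)
    se = np.sqrt(p * (1 - p) / 500)
    assert abs(frac - p) <= 3 * se


def test_daily_fast_path_matches_truth_structure(daily_cohort):
    _, (feat, od, fates, ph, meta, truth) = daily_cohort
    assert set(truth["true_fate"]) <= {"alive", "dead", "vanished"}
    dead = truth[truth["true_fate"] == "dead"]
    assert (pd.to_datetime(dead["true_death_date"])
            <= pd.to_datetime(dead["last_record_date"])).all()
    # measured daily ODBA sits on the true activity level
    j = truth.iloc[0]
    mine = od[od["individual_id"] == j["individual_id"]]
    alive_med = mine["odba_median"][mine["odba_median"] > 0].median()
    assert alive_med == pytest.approx(j["odba"], abs=0.1)
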