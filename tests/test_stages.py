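"""Stage windows, survival-table assembly, bookkeeping identities."""

import numpy as np
import pandas as pd
import pytest

from storksurv.stages import (build_stage_table, overall_km_input,
                              stage_windows)


class TestWindows:
    def test_direct_rule(self):
        w = stage_windows("2015-06-20", "2015-08-15", 2015)
        assert w["postfledging"] == (pd.Timestamp("2015-06-20"),
                                     pd.Timestamp("2015-08-15"))
        assert w["migration"] == (pd.Timestamp("2015-08-15"),
                                  pd.Timestamp("2015-09-30"))
        assert w["winter"] == (pd.Timestamp("2015-10-01"),
                               pd.Timestamp("2016-02-28"))

    def test_departure_after_september_drops_migration(self, caplog):
        w = stage_windows("2015-06-20", "2015-10-05", 2015)
        assert "migration" not in w

    def test_missing_departure_only_postfledging(self):
        w = stage_windows("2015-06-20", None, 2015)
        assert set(w) == {"postfledging"}

    def test_zero_length_postfledging_flagged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            stage_windows("2015-06-20", "2015-06-20", 2015)
        assert any("zero length" in m for m in caplog.messages)


def _toy_inputs():
    """Three individuals: death in migration, survivor, early vanisher."""
    dates = pd.date_range("2015-06-20", "2016-02-28")
    feats, odbas = [], []
    for ind in ("d", "s", "v"):
        feats.append(pd.DataFrame({
            "individual_id": ind, "date": dates,
            "log_displacement": np.log(5.0),
        }))
        odbas.append(pd.DataFrame({
            "individual_id": ind, "date": dates, "odba_median": 3.0,
        }))
    fates = pd.DataFrame([
        ("d", "dead", pd.Timestamp("2015-08-25"),
         pd.Timestamp("2015-09-05")),
        ("s", "alive", None, pd.Timestamp("2016-02-28")),
        ("v", "vanished", None, pd.Timestamp("2015-08-20")),
    ], columns=["individual_id", "status", "death_date",
                "last_record_date"])
    ph = pd.DataFrame([
        ("d", pd.Timestamp("2015-06-25"), 176, pd.Timestamp("2015-08-15"),
         227, None, None),
        ("s", pd.Timestamp("2015-06-25"), 176, pd.Timestamp("2015-08-15"),
         227, "Europe", 38.0),
        ("v", pd.Timestamp("2015-06-25"), 176, pd.Timestamp("2015-08-15"),
         227, None, None),
    ], columns=["individual_id", "fledging_date", "fledging_doy",
                "departure_date", "departure_doy", "wintering_region",
                "southernmost_lat"])
    meta = pd.DataFrame({
        "individual_id": ["d", "s", "v"], "tag_year": 2015,
        "sex": ["F", "M", "F"], "hatch_rank": [1, 2, 1],
        "n_siblings": [2, 1, 0],
    })
    feats = pd.concat(feats, ignore_index=True)
    odbas = pd.concat(odbas, ignore_index=True)
    return feats, odbas, fates, ph, meta


class TestStageTable:
    def test_event_and_censor_times(self):
        feats, odbas, fates, ph, meta = _toy_inputs()
        mig = build_stage_table(feats, odbas, fates, ph, meta, "migration")
        mig = mig.set_index("individual_id")
        # death Aug 25, window opens Aug 15 -> 10 days, event
        assert mig.loc["d", "time_days"] == 10 and mig.loc["d",
                                                           "event"] == 1
        # survivor censored at the 46-day window
        assert mig.loc["s", "time_days"] == 46 and mig.loc["s",
                                                           "event"] == 0
        # vanished Aug 20 -> censored at 5 days, flagged
        assert mig.loc["v", "time_days"] == 5 and mig.loc["v",
                                                          "event"] == 0
        assert bool(mig.loc["v", "vanished"])

    def test_dead_before_stage_excluded(self):
        feats, odbas, fates, ph, meta = _toy_inputs()
        win = build_stage_table(feats, odbas, fates, ph, meta, "winter")
        assert set(win["individual_id"]) == {"s"}

    def test_stage_covariates_and_carry_over(self):
        feats, odbas, fates, ph, meta = _toy_inputs()
        win = build_stage_table(feats, odbas, fates, ph, meta, "winter")
        row = win.iloc[0]
        assert row["odba"] == pytest.approx(3.0)
        assert row["log_dist"] == pytest.approx(np.log(5.0))
        assert row["odba_migration"] == pytest.approx(3.0)
        assert row["wintering_region"] == "Europe"
        assert row["stratum"] == 2015

    def test_row_counts_telescope(self, daily_cohort):
        """n(next stage) = n(stage) - deaths - vanished, per stage."""
        _, (feat, od, fates, ph, meta, truth) = daily_cohort
        tabs = {s: build_stage_table(feat, od, fates, ph, meta, s)
                for s in ("postfledging", "migration", "winter")}
        for a, b in (("postfledging", "migration"),
                     ("migration", "winter")):
            ta = tabs[a]
            expected = len(ta) - int(ta["event"].sum()) - int(
                ta["vanished"].sum())
            assert len(tabs[b]) == expected
        for t in tabs.values():
            assert t["individual_id"].is_unique
            assert (t["time_days"] > 0).all()


class TestOverallInput:
    def test_time_origins_and_censoring(self):
        feats, odbas, fates, ph, meta = _toy_inputs()
        km_in = overall_km_input(fates, ph, meta).set_index(
            "individual_id")
        # death Aug 25, fledged Jun 25 -> 61 days, event
        assert km_in.loc["d", "time_days"] == 61
        assert km_in.loc["d", "event"] == 1
        # survivor censored at Feb 28 (248 days after fledging)
        assert km_in.loc["s", "time_days"] == 248
        assert km_in.loc["s", "event"] == 0
        # vanished censored at its last record (56 days)
        assert km_in.loc["v", "time_days"] == 56
        assert km_in.loc["v", "event"] == 0

    def test_fate_categories_sum_to_cohort(self, daily_cohort):
        _, (feat, od, fates, ph, meta, truth) = daily_cohort
        counts = fates["status"].value_counts()
        assert counts.sum() == len(meta)
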