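"""Distance kernel, daily displacement, phenology rules, regions."""

import numpy as np
import pandas as pd
import pytest

from storksurv.tracks import (daily_features, detect_departure,
                              detect_fledging, haversine_km,
                              wintering_region)


def _daily(dates, lats, lons=None):
    lons = lons if lons is not None else [9.0] * len(lats)
    return pd.DataFrame({
        "individual_id": "a",
        "date": pd.to_datetime(dates),
        "first_fix_lat": lats,
        "first_fix_lon": lons,
    })


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_km(0, 0, 0, 0) == 0.0

    def test_one_degree_latitude(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.01)

    def test_quarter_circumference(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(10007.54,
                                                          abs=0.01)

    def test_symmetry(self):
        a = haversine_km(48.2, 9.1, 36.0, -5.5)
        b = haversine_km(36.0, -5.5, 48.2, 9.1)
        assert a == pytest.approx(b, rel=1e-12)


class TestDailyFeatures:
    def _gps(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "timestamp",
                                           "lat", "lon"]).assign(
            timestamp=lambda d: pd.to_datetime(d["timestamp"]))

    def test_one_degree_south_is_111km(self):
        gps = self._gps([
            ("a", "2015-08-01 05:00", 48.0, 8.0),
            ("a", "2015-08-02 05:00", 47.0, 8.0),
        ])
        f = daily_features(gps)
        assert f["displacement_km"].iloc[1] == pytest.approx(111.19,
                                                             abs=0.01)

    def test_gap_days_have_no_displacement(self):
        gps = self._gps([
            ("a", "2015-08-10 05:00", 48.0, 8.0),
            ("a", "2015-08-12 05:00", 47.0, 8.0),
        ])
        f = daily_features(gps)
        assert np.isnan(f["displacement_km"].iloc[1])

    def test_zero_displacement_floored_before_log(self):
        gps = self._gps([
            ("a", "2015-08-01 05:00", 48.0, 8.0),
            ("a", "2015-08-02 05:00", 48.0, 8.0),
        ])
        f = daily_features(gps)
        assert f["displacement_km"].iloc[1] == 0.0
        assert f["log_displacement"].iloc[1] == pytest.approx(
            np.log(0.001))

    def test_first_fix_used_not_later_ones(self):
        gps = self._gps([
            ("a", "2015-08-01 05:00", 48.0, 8.0),
            ("a", "2015-08-01 19:00", 40.0, 8.0),  # later fix ignored
            ("a", "2015-08-02 05:00", 48.0, 8.0),
        ])
        f = daily_features(gps)
        assert f["displacement_km"].iloc[1] == pytest.approx(0.0, abs=1e-9)


class TestFledging:
    def test_two_consecutive_far_days(self):
        # ~0.1, 0.6, 0.7 km from the nest
        d = _daily(["2015-06-29", "2015-06-30", "2015-07-01"],
                   [48.0009, 48.0054, 48.0063])
        out = detect_fledging(d, 48.0, 9.0)
        assert out == pd.Timestamp("2015-06-30")

    def test_alternating_never_fledges(self):
        d = _daily(["2015-06-29", "2015-06-30", "2015-07-01",
                    "2015-07-02"],
                   [48.0054, 48.0018, 48.0054, 48.0018])
        assert detect_fledging(d, 48.0, 9.0) is None

    def test_fledged_from_record_start(self):
        d = _daily(["2015-06-29", "2015-06-30"], [48.0054, 48.0063])
        assert detect_fledging(d, 48.0, 9.0) == pd.Timestamp("2015-06-29")


class TestDeparture:
    def test_first_big_southward_step(self):
        d = _daily(["2015-08-20", "2015-08-21", "2015-08-22"],
                   [48.0, 47.9, 47.5])
        assert detect_departure(d) == pd.Timestamp("2015-08-22")

    def test_northward_never_departs(self):
        d = _daily(["2015-08-20", "2015-08-21"], [48.0, 48.5])
        assert detect_departure(d) is None

    def test_threshold_inclusive(self):
        d = _daily(["2015-08-20", "2015-08-21"], [48.0, 48.0 - 0.38])
        assert detect_departure(d) == pd.Timestamp("2015-08-21")


class TestRegions:
    def _fixes(self, lats):
        return pd.DataFrame({
            "timestamp": pd.date_range("2015-11-01", periods=len(lats)),
            "lat": lats, "lon": [0.0] * len(lats),
        })

    WINDOW = (pd.Timestamp("2015-10-01"), pd.Timestamp("2016-02-28"))

    @pytest.mark.parametrize("lat,region", [
        (38.7, "Europe"), (36.0, "Europe"), (25.0, "NorthAfrica"),
        (35.99, "NorthAfrica"), (20.0, "NorthAfrica"),
        (14.9, "SubSaharan"), (19.99, "SubSaharan"),
    ])
    def test_threshold_rules(self, lat, region):
        got, south = wintering_region(self._fixes([45.0, lat]), self.WINDOW)
        assert got == region
        assert south == lat

    def test_partition_no_gaps(self):
        """Every latitude below 90 falls in exactly one class."""
        for lat in np.linspace(-89, 89, 1001):
            got, _ = wintering_region(self._fixes([lat]), self.WINDOW)
            assert got in {"Europe", "NorthAfrica", "SubSaharan"}

    def test_no_winter_fixes(self):
        fx = pd.DataFrame({"timestamp": [pd.Timestamp("2015-08-01")],
                           "lat": [48.0], "lon": [9.0]})
        assert wintering_region(fx, self.WINDOW) == (None, None)


def test_phenology_recovers_generator_truth(stream_cohort):
    """Detected fledging/departure match truth to the day."""
    from storksurv.tracks import compute_phenology

    _, cohort = stream_cohort
    ph = compute_phenology(cohort.gps, cohort.metadata)
    merged = ph.merge(cohort.truth, on="individual_id")
    both = merged.dropna(subset=["fledging_doy", "departure_doy"])
    assert len(both) >= 3
    assert (both["fledging_doy"] == both["true_fledge_doy"]).all()
    assert (both["departure_doy"] == both["true_depart_doy"]).all()
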