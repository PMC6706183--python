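"""Mortality-criterion rules and the combined fate verdict."""

import numpy as np
import pandas as pd
import pytest

from storksurv.fate import (classify_fate, detect_flatline,
                            detect_stationary, near_structures)
from storksurv.io import AccBurst

T0 = pd.Timestamp("2015-09-01 02:00:00")


def _bursts(hours, flat, ind="a"):
    """One burst per entry of ``hours``; flat or noisy."""
    rng = np.random.default_rng(0)
    out = []
    for h, is_flat in zip(hours, flat):
        if is_flat:
            s = np.full((40, 3), 2000.0)
        else:
            s = 2000.0 + rng.normal(0, 5, size=(40, 3))
        out.append(AccBurst(ind, T0 + pd.Timedelta(hours=float(h)), 20.0,
                            s))
    return out


class TestFlatline:
    def test_thirty_hours_flat_detected(self):
        hours = np.arange(0, 36, 2.0)
        bursts = _bursts(hours, [h >= 4 for h in hours])
        start = detect_flatline(bursts)
        assert start == T0 + pd.Timedelta(hours=4)

    def test_twenty_hours_not_enough(self):
        hours = np.arange(0, 40, 2.0)
        bursts = _bursts(hours, [4 <= h < 24 for h in hours])  # 20 h span
        assert detect_flatline(bursts) is None

    def test_one_varying_axis_breaks_flatness(self):
        hours = np.arange(0, 40, 2.0)
        bursts = _bursts(hours, [True] * len(hours))
        rng = np.random.default_rng(1)
        for b in bursts:  # X, Y constant; Z jitters beyond tolerance
            b.samples[:, 2] += rng.normal(0, 5, len(b.samples))
        assert detect_flatline(bursts) is None


def _fixes(day_offsets_lats_lons, ind="a"):
    rows = []
    for d, la, lo in day_offsets_lats_lons:
        for h in (3, 9, 15):
            rows.append((ind, T0 + pd.Timedelta(days=d, hours=h - 2),
                         la, lo))
    return pd.DataFrame(rows, columns=["individual_id", "timestamp",
                                       "lat", "lon"])


class TestStationary:
    def test_four_tight_days_detected(self):
        fx = _fixes([(d, 48.0, 9.0) for d in range(4)])
        assert detect_stationary(fx) == T0.normalize()

    def test_three_days_is_not_more_than_three(self):
        fx = _fixes([(d, 48.0, 9.0) for d in range(3)]
                    + [(3, 48.5, 9.0)])
        assert detect_stationary(fx) is None

    def test_excursion_breaks_the_run(self):
        fx = _fixes([(0, 48.0, 9.0), (1, 48.0, 9.0),
                     (2, 48.005, 9.0),  # ~500 m away
                     (3, 48.0, 9.0), (4, 48.0, 9.0)])
        assert detect_stationary(fx) is None

    def test_pairwise_rule_variant(self):
        fx = _fixes([(d, 48.0, 9.0) for d in range(5)])
        assert detect_stationary(fx, rule="pairwise") == T0.normalize()


class TestStructures:
    LAYER = pd.DataFrame({"lat": [48.0], "lon": [9.0], "radius_m": [50.0]})

    def test_last_fix_near_structure(self):
        fx = _fixes([(0, 47.0, 9.0), (1, 48.00005, 9.0)])
        assert near_structures(fx, self.LAYER)

    def test_empty_layer_false(self):
        fx = _fixes([(0, 48.0, 9.0)])
        assert not near_structures(fx, None)
        assert not near_structures(fx, self.LAYER.iloc[:0])

    def test_far_fixes_false(self):
        fx = _fixes([(0, 47.0, 10.0)])
        assert not near_structures(fx, self.LAYER)


class TestClassify:
    END = pd.Timestamp("2015-10-20")

    def test_earliest_criterion_sets_death_day(self):
        """Flatline from day 4, stationary from day 5: death = day 4."""
        hours = np.arange(0, 24 * 12, 2.0)
        bursts = _bursts(hours, [h >= 96 for h in hours])
        fx = _fixes([(d, 48.0 - 0.2 * max(0, 5 - d), 9.0)
                     for d in range(12)])
        rec = classify_fate(fx, bursts, None, self.END)
        assert rec.status == "dead"
        assert rec.death_date == (T0 + pd.Timedelta(days=4)).normalize()
        assert rec.criterion == "acc_flatline"

    def test_mobile_early_stop_is_vanished(self):
        fx = _fixes([(d, 48.0 - 0.3 * d, 9.0) for d in range(5)])
        bursts = _bursts(np.arange(0, 24 * 5, 3.0), [False] * 40)
        rec = classify_fate(fx, bursts, None, self.END)
        assert rec.status == "vanished"
        assert rec.death_date is None

    def test_recording_to_study_end_is_alive(self):
        days = int((self.END - T0.normalize()).days) + 1
        fx = _fixes([(d, 48.0 - 0.1 * d, 9.0) for d in range(days)])
        bursts = _bursts(np.arange(0, 24 * days, 6.0), [False] * (4 * days))
        rec = classify_fate(fx, bursts, None, self.END)
        assert rec.status == "alive"

    def test_structure_proximity_needs_early_end(self):
        layer = TestStructures.LAYER
        fx = _fixes([(0, 47.0, 9.0), (1, 48.00005, 9.0)])
        rec = classify_fate(fx, [], layer, self.END)
        assert rec.status == "dead"
        assert rec.criterion == "structure_proximity"

    def test_field_override_wins(self):
        fx = _fixes([(d, 48.0 - 0.3 * d, 9.0) for d in range(5)])
        rec = classify_fate(fx, [], None, self.END,
                            overrides={"a": "2015-09-03"})
        assert rec.status == "dead"
        assert rec.criterion == "field_confirmed"
        assert rec.death_date == pd.Timestamp("2015-09-03")

    def test_no_data_is_vanished_with_warning(self):
        rec = classify_fate(pd.DataFrame(columns=["individual_id",
                                                  "timestamp", "lat",
                                                  "lon"]),
                            [], None, self.END, individual_id="x")
        assert rec.status == "vanished"

    def test_monotone_adding_post_death_data(self):
        """Appending more post-death days never moves death later."""
        hours = np.arange(0, 24 * 8, 2.0)
        bursts = _bursts(hours, [h >= 48 for h in hours])
        fx = _fixes([(d, 48.0, 9.0) for d in range(8)])
        rec1 = classify_fate(fx, bursts, None, self.END)
        hours2 = np.arange(0, 24 * 16, 2.0)
        bursts2 = _bursts(hours2, [h >= 48 for h in hours2])
        fx2 = _fixes([(d, 48.0, 9.0) for d in range(16)])
        rec2 = classify_fate(fx2, bursts2, None, self.END)
        assert rec1.status == rec2.status == "dead"
        assert rec2.death_date <= rec1.death_date
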