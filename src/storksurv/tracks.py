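"""Daily movement features and migration phenology from GPS fixes.

All definitions operate on the *first fix of each UTC calendar day*:

* daily displacement — great-circle distance between the first fixes of
  two calendar-consecutive days (missing across gaps), log-transformed
  with a 0.001 km floor;
* fledging — first of two consecutive days with nest distance > 500 m;
* departure — first day whose first-fix latitude lies at least 0.38
  degrees south of the previous day's (about 50 km), inclusive;
* wintering region — class of the southernmost first-winter latitude:
  Europe north of the Strait of Gibraltar (taken as 36.0 N), North
  Africa from 20 N to the strait, Sub-Saharan Africa below 20 N
  (nominally the 12-20 N band; positions south of 12 N are classed
  Sub-Saharan with a warning).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["haversine_km", "daily_features", "detect_fledging",
           "detect_departure", "wintering_region", "compute_phenology",
           "EARTH_RADIUS_KM", "GIBRALTAR_LAT", "NORTH_AFRICA_SOUTH_LAT"]

EARTH_RADIUS_KM = 6371.0
GIBRALTAR_LAT = 36.0
NORTH_AFRICA_SOUTH_LAT = 20.0
SUBSAHARAN_SOUTH_LAT = 12.0
FLEDGE_DISTANCE_KM = 0.5
DEPARTURE_LAT_DROP = -0.38
LOG_FLOOR_KM = 0.001


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (spherical Earth, R = 6371.0 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(
        dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return float(d) if np.isscalar(lat1) or d.ndim == 0 else d


def first_daily_fixes(gps: pd.DataFrame) -> pd.DataFrame:
    """First fix per individual per UTC calendar day."""
    df = gps.sort_values(["individual_id", "timestamp"], kind="stable")
    df = df.assign(date=df["timestamp"].dt.normalize())
    return (df.groupby(["individual_id", "date"], as_index=False)
            .first()[["individual_id", "date", "timestamp", "lat", "lon"]])


def daily_features(gps: pd.DataFrame) -> pd.DataFrame:
    """Per-individual, per-day displacement features.

    Displacement is defined only for calendar-consecutive day pairs and
    assigned to the later day; the natural log uses a 0.001 km floor.
    """
    first = first_daily_fixes(gps)
    out = []
    for ind, g in first.groupby("individual_id", sort=False):
        g = g.sort_values("date").reset_index(drop=True)
        prev_date = g["date"].shift(1)
        consecutive = (g["date"] - prev_date).dt.days == 1
        disp = haversine_km(g["lat"].shift(1).to_numpy(),
                            g["lon"].shift(1).to_numpy(),
                            g["lat"].to_numpy(), g["lon"].to_numpy())
        disp = np.where(consecutive.to_numpy(), disp, np.nan)
        out.append(pd.DataFrame({
            "individual_id": ind,
            "date": g["date"],
            "doy": g["date"].dt.dayofyear,
            "first_fix_lat": g["lat"],
            "first_fix_lon": g["lon"],
            "displacement_km": disp,
            "log_displacement": np.log(np.maximum(disp, LOG_FLOOR_KM)),
        }))
    cols = ["individual_id", "date", "doy", "first_fix_lat",
            "first_fix_lon", "displacement_km", "log_displacement"]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)[cols]


def detect_fledging(daily: pd.DataFrame, nest_lat: float, nest_lon: float,
                    threshold_km: float = FLEDGE_DISTANCE_KM):
    """First of two consecutive days with nest distance > threshold.

    ``daily`` is one individual's first-daily-fix frame.  Returns the
    fledging date (Timestamp) or None.
    """
    g = daily.sort_values("date").reset_index(drop=True)
    dist = haversine_km(g["first_fix_lat"].to_numpy(),
                        g["first_fix_lon"].to_numpy(), nest_lat, nest_lon)
    dates = g["date"].reset_index(drop=True)
    far = dist > threshold_km
    for i in range(len(g) - 1):
        next_is_tomorrow = (dates[i + 1] - dates[i]).days == 1
        if far[i] and next_is_tomorrow and far[i + 1]:
            return dates[i]
    return None


def detect_departure(daily: pd.DataFrame,
                     drop_threshold: float = DEPARTURE_LAT_DROP):
    """First day whose first-fix latitude drops >= 0.38 degrees from the
    previous day's (inclusive at the threshold).  Returns date or None."""
    g = daily.sort_values("date").reset_index(drop=True)
    lat = g["first_fix_lat"].to_numpy()
    dates = g["date"].reset_index(drop=True)
    for i in range(1, len(g)):
        if (dates[i] - dates[i - 1]).days != 1:
            continue
        if lat[i] - lat[i - 1] <= drop_threshold:
            return dates[i]
    return None


def wintering_region(fixes: pd.DataFrame, winter_window):
    """Wintering-region class from the southernmost first-winter fix.

    ``winter_window`` is a (start, end) pair of timestamps.  Returns
    ``(region, southernmost_lat)`` or ``(None, None)`` when the window
    holds no fixes.
    """
    start, end = winter_window
    sel = fixes[(fixes["timestamp"] >= start) & (fixes["timestamp"] <= end)]
    if sel.empty:
        return None, None
    lat = float(sel["lat"].min())
    if lat >= GIBRALTAR_LAT:
        region = "Europe"
    elif lat >= NORTH_AFRICA_SOUTH_LAT:
        region = "NorthAfrica"
    else:
        region = "SubSaharan"
        if lat < SUBSAHARAN_SOUTH_LAT:
            logger.warning(
                "southernmost latitude %.2f below the 12 N band; "
                "classed SubSaharan", lat)
    return region, lat


def compute_phenology(gps: pd.DataFrame, metadata: pd.DataFrame
                      ) -> pd.DataFrame:
    """Fledging, departure and wintering region for every individual.

    ``metadata`` supplies nest coordinates and the tag year (used to
    anchor the first-winter window, 1 Oct to 28 Feb).
    """
    daily = first_daily_fixes(gps).rename(
        columns={"lat": "first_fix_lat", "lon": "first_fix_lon"})
    rows = []
    meta = metadata.set_index("individual_id")
    for ind, g in daily.groupby("individual_id", sort=False):
        if ind not in meta.index:
            logger.warning("no metadata for %s; skipped", ind)
            continue
        m = meta.loc[ind]
        year = int(m["tag_year"])
        fledge = detect_fledging(g, float(m["nest_lat"]),
                                 float(m["nest_lon"]))
        depart = detect_departure(g)
        if fledge is not None and depart is not None and depart < fledge:
            depart = None  # a pre-fledging latitude artefact, not migration
        window = (pd.Timestamp(year=year, month=10, day=1),
                  pd.Timestamp(year=year + 1, month=2, day=28,
                               hour=23, minute=59, second=59))
        fx = gps[gps["individual_id"] == ind]
        region, south = wintering_region(fx, window)
        rows.append({
            "individual_id": ind,
            "fledging_date": fledge,
            "fledging_doy": None if fledge is None else int(
                fledge.dayofyear),
            "departure_date": depart,
            "departure_doy": None if depart is None else int(
                depart.dayofyear),
            "wintering_region": region,
            "southernmost_lat": south,
        })
    return pd.DataFrame(rows)
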