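"""Rule-based mortality detection from telemetry signatures.

An individual is classed dead when (a) the accelerometer flat-lines for
more than 24 hours, (b) its GPS positions stay inside a 100 m radius
for more than three consecutive days, or (c) the record stream ends
with the last fixes near anthropogenic structures.  The death day is
the first stationary or motionless day.  Birds whose stream ends with
none of the criteria met are "vanished" (treated as censored
downstream); birds recording to the study end are alive.

Operational choices the rules leave open: "radius of 100 m" is read as
distance to the run's centroid (a max-pairwise-distance <= 200 m
variant is available); "more than three days" and "more than 24 hr"
are strict inequalities; per-axis flatness tolerance defaults to one
raw unit, since real tags jitter even when motionless.  The structure
criterion is a point-buffer approximation of what was a manual
map-inspection step, and is flagged as approximate in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import haversine_km

logger = logging.getLogger(__name__)

__all__ = ["FateRecord", "detect_flatline", "detect_stationary",
           "near_structures", "classify_fate", "classify_cohort"]

FLAT_EPS_DEFAULT = 1.0
FLATLINE_HOURS = 24.0
STATIONARY_RADIUS_M = 100.0
STATIONARY_MIN_DAYS = 3  # strictly more than this many consecutive days
STRUCTURE_BUFFER_M = 50.0
STRUCTURE_LAST_K = 20


@dataclass
class FateRecord:
    individual_id: str
    status: str  # alive | dead | vanished
    death_date: pd.Timestamp | None
    criterion: str  # acc_flatline | gps_stationary | structure_proximity
    #                 | field_confirmed | none
    last_record_date: pd.Timestamp | None

    def __post_init__(self):
        if (self.status == "dead") != (self.death_date is not None):
            raise ValueError("status 'dead' iff death_date is set")


def detect_flatline(bursts, flat_eps: float = FLAT_EPS_DEFAULT,
                    min_hours: float = FLATLINE_HOURS):
    """Start of the earliest flat accelerometer interval, or None.

    A burst is flat when every axis has sample range <= ``flat_eps``;
    an interval qualifies when a maximal run of flat bursts spans more
    than ``min_hours`` from the first flat burst's start to the last
    one's end.
    """
    if not bursts:
        return None
    flat = np.array([
        bool(np.all(np.ptp(b.samples, axis=0) <= flat_eps)) for b in bursts
    ])
    n = len(bursts)
    i = 0
    while i < n:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flat[j + 1]:
            j += 1
        span_h = (
            (bursts[j].start - bursts[i].start).total_seconds()
            + bursts[j].duration_s
        ) / 3600.0
        if span_h > min_hours:
            return bursts[i].start
        i = j + 1
    return None


def _day_groups(fixes: pd.DataFrame):
    df = fixes.sort_values("timestamp")
    days = df["timestamp"].dt.normalize()
    return [(day, sub) for day, sub in df.groupby(days)]


def detect_stationary(fixes: pd.DataFrame,
                      radius_m: float = STATIONARY_RADIUS_M,
                      min_days: int = STATIONARY_MIN_DAYS,
                      rule: str = "centroid"):
    """Start day of the earliest stationary GPS interval, or None.

    Looks for a run of more than ``min_days`` calendar-consecutive days
    whose fixes all lie within ``radius_m`` of the run's centroid
    (``rule="centroid"``), or whose maximum pairwise distance stays
    within ``2 * radius_m`` (``rule="pairwise"``).
    """
    if fixes.empty:
        return None
    groups = _day_groups(fixes)
    days = [d for d, _ in groups]
    # quick per-day pre-filter: a day whose own spread already exceeds the
    # radius can never belong to a qualifying run
    tight = []
    for _, sub in groups:
        la, lo = sub["lat"].to_numpy(), sub["lon"].to_numpy()
        d = haversine_km(la, lo, la.mean(), lo.mean()) * 1000.0
        tight.append(bool(np.max(d) <= radius_m))
    n = len(groups)
    i = 0
    while i < n:
        if not tight[i]:
            i += 1
            continue
        # extend a candidate run of calendar-consecutive tight days
        j = i
        while (j + 1 < n and tight[j + 1]
               and (days[j + 1] - days[j]).days == 1):
            j += 1
        # within the maximal tight block, find the earliest qualifying run
        start = _scan_block(groups[i:j + 1], radius_m, min_days, rule)
        if start is not None:
            return start
        i = j + 1
    return None


def _scan_block(block, radius_m, min_days, rule):
    for s in range(len(block)):
        lats = lons = None
        for e in range(s, len(block)):
            sub = block[e][1]
            la, lo = sub["lat"].to_numpy(), sub["lon"].to_numpy()
            lats = la if lats is None else np.concatenate([lats, la])
            lons = lo if lons is None else np.concatenate([lons, lo])
            run_days = e - s + 1
            if rule == "centroid":
                d = haversine_km(lats, lons, lats.mean(), lons.mean()) * 1000
                ok = np.max(d) <= radius_m
            else:
                ok = _max_pairwise_m(lats, lons) <= 2 * radius_m
            if not ok:
                break
            if run_days > min_days:
                return block[s][0]
    return None


def _max_pairwise_m(lats, lons):
    if len(lats) > 400:  # subsample; pairwise cost grows quadratically
        idx = np.linspace(0, len(lats) - 1, 400).astype(int)
        lats, lons = lats[idx], lons[idx]
    d = haversine_km(lats[:, None], lons[:, None], lats[None, :],
                     lons[None, :]) * 1000.0
    return float(np.max(d))


def near_structures(fixes: pd.DataFrame, structure_layer,
                    buffer_m: float = STRUCTURE_BUFFER_M,
                    last_k: int = STRUCTURE_LAST_K) -> bool:
    """True if any of the last ``last_k`` fixes falls within the buffer
    of any structure point.  ``structure_layer`` is a frame with
    ``lat, lon`` and optional per-point ``radius_m``."""
    if structure_layer is None or len(structure_layer) == 0 or fixes.empty:
        return False
    tail = fixes.sort_values("timestamp").tail(last_k)
    s_lat = structure_layer["lat"].to_numpy(float)
    s_lon = structure_layer["lon"].to_numpy(float)
    if "radius_m" in structure_layer:
        radii = structure_layer["radius_m"].to_numpy(float)
    else:
        radii = np.full(len(s_lat), buffer_m)
    d = haversine_km(tail["lat"].to_numpy()[:, None],
                     tail["lon"].to_numpy()[:, None],
                     s_lat[None, :], s_lon[None, :]) * 1000.0
    return bool(np.any(d <= radii[None, :]))


def classify_fate(fixes: pd.DataFrame, bursts, structure_layer,
                  study_end, individual_id: str = None,
                  flat_eps: float = FLAT_EPS_DEFAULT,
                  overrides: dict | None = None,
                  start_date=None) -> FateRecord:
    """Combine the three criteria into one fate verdict.

    ``overrides`` maps individual id to a confirmed death date
    (emulating field confirmation); an override takes precedence.
    Death date is the earliest triggering interval's start day.
    ``start_date`` (typically the fledging date) restricts the criteria
    to records from that day on: a nestling sitting on its nest is
    stationary by the 100 m rule but obviously not dead, and survival
    monitoring starts at fledging anyway.
    """
    study_end = pd.Timestamp(study_end).normalize()
    if start_date is not None and not pd.isna(start_date):
        start_date = pd.Timestamp(start_date).normalize()
        if len(fixes):
            fixes = fixes[fixes["timestamp"] >= start_date]
        bursts = [b for b in bursts if b.start >= start_date]
    if individual_id is None:
        individual_id = (fixes["individual_id"].iloc[0] if len(fixes)
                         else bursts[0].individual_id if bursts else "?")
    last_gps = fixes["timestamp"].max() if len(fixes) else None
    last_acc = bursts[-1].start if bursts else None
    candidates = [d for d in (last_gps, last_acc) if d is not None]
    if not candidates:
        logger.warning("%s: no records at all; vanished at deployment start",
                       individual_id)
        return FateRecord(individual_id, "vanished", None, "none", None)
    last_record = max(candidates).normalize()

    if overrides and individual_id in overrides:
        dd = pd.Timestamp(overrides[individual_id]).normalize()
        return FateRecord(individual_id, "dead", dd, "field_confirmed",
                          last_record)

    hits = []
    flat = detect_flatline(bursts, flat_eps=flat_eps) if bursts else None
    if flat is not None:
        hits.append((pd.Timestamp(flat).normalize(), "acc_flatline"))
    stat = detect_stationary(fixes) if len(fixes) else None
    if stat is not None:
        hits.append((pd.Timestamp(stat).normalize(), "gps_stationary"))
    ended_early = last_record < study_end
    if ended_early and near_structures(fixes, structure_layer):
        hits.append((last_record, "structure_proximity"))
    if hits:
        hits.sort(key=lambda h: h[0])
        day, crit = hits[0]
        return FateRecord(individual_id, "dead", day, crit, last_record)
    if ended_early:
        return FateRecord(individual_id, "vanished", None, "none",
                          last_record)
    return FateRecord(individual_id, "alive", None, "none", last_record)


def classify_cohort(gps: pd.DataFrame, bursts_by_individual: dict,
                    structure_layer, study_end, overrides=None,
                    flat_eps: float = FLAT_EPS_DEFAULT,
                    start_dates=None) -> pd.DataFrame:
    """Fate table for a whole cohort (one row per individual).

    ``study_end`` and ``start_dates`` may be scalars or per-individual
    mappings (``start_dates`` typically the fledging dates).
    """
    ids = sorted(set(gps["individual_id"]).union(bursts_by_individual))
    records = []
    for ind in ids:
        fx = gps[gps["individual_id"] == ind]
        bs = bursts_by_individual.get(ind, [])
        se = study_end[ind] if isinstance(study_end, dict) else study_end
        sd = (start_dates.get(ind) if isinstance(start_dates, dict)
              else start_dates)
        rec = classify_fate(fx, bs, structure_layer, se, individual_id=ind,
                            flat_eps=flat_eps, overrides=overrides,
                            start_date=sd)
        records.append({
            "individual_id": rec.individual_id,
            "status": rec.status,
            "death_date": rec.death_date,
            "criterion": rec.criterion,
            "last_record_date": rec.last_record_date,
        })
    return pd.DataFrame(records)
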