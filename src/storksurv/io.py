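"""Movebank-style CSV input/output and the cohort exclusion filter.

GPS streams use the Movebank column dialect
``individual-local-identifier, timestamp, location-lat, location-long``
with timestamps ``yyyy-MM-dd HH:mm:ss.SSS`` in UTC; ACC streams use
``individual-local-identifier, start-timestamp,
eobs:acceleration-sampling-frequency-per-axis, eobs:accelerations-raw``
where the raw field is a space-separated X Y Z interleaved sample
string.  Column names can be overridden per file via a mapping.

Malformed rows (out-of-bounds coordinates, non-numeric samples, raw
strings whose length is not divisible by three) are rejected and
counted, never silently kept.  Duplicate timestamps within an
individual keep the first occurrence.  All timestamps are interpreted
as UTC; values are stored timezone-naive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GPS_COLUMNS", "ACC_COLUMNS", "AccBurst", "GpsReadResult",
    "AccReadResult", "read_gps", "read_acc", "write_gps", "write_acc",
    "read_metadata", "apply_cohort_exclusions", "EXCLUSION_FLAGS",
]

GPS_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lat": "location-lat",
    "lon": "location-long",
}
ACC_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "start": "start-timestamp",
    "hz": "eobs:acceleration-sampling-frequency-per-axis",
    "raw": "eobs:accelerations-raw",
}
EXCLUSION_FLAGS = ("not_fledged", "eastern_route", "device_fault",
                   "late_departure")
_TS_FORMAT = "%Y-%m-%d %H:%M:%S.%f"


@dataclass
class AccBurst:
    """One tri-axial acceleration burst.

    ``samples`` is an (n, 3) float array of raw sensor units in X, Y, Z
    order; the burst duration is ``len(samples) / hz`` seconds.
    """

    individual_id: str
    start: pd.Timestamp
    hz: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        if self.hz <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.samples) < 1:
            raise ValueError("burst needs at least one sample")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.hz

    @property
    def date(self):
        return self.start.date()


@dataclass
class GpsReadResult:
    data: pd.DataFrame  # individual_id, timestamp, lat, lon (sorted)
    n_rejected: int = 0
    n_duplicates: int = 0

    @property
    def individuals(self):
        return list(self.data["individual_id"].unique())


@dataclass
class AccReadResult:
    bursts: dict = field(default_factory=dict)  # id -> list[AccBurst]
    n_rejected: int = 0


def _apply_map(default: dict, override) -> dict:
    m = dict(default)
    if override:
        m.update(override)
    return m


def read_gps(path, column_map=None) -> GpsReadResult:
    """Read a Movebank-style GPS CSV into a tidy, per-individual-sorted
    frame, rejecting rows with unparsable or out-of-bounds values."""
    cols = _apply_map(GPS_COLUMNS, column_map)
    raw = pd.read_csv(path, dtype={cols["individual_id"]: str})
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"GPS file {path} missing column(s): {missing}")
    df = pd.DataFrame(
        {
            "individual_id": raw[cols["individual_id"]],
            "timestamp": pd.to_datetime(raw[cols["timestamp"]],
                                        errors="coerce", utc=True),
            "lat": pd.to_numeric(raw[cols["lat"]], errors="coerce"),
            "lon": pd.to_numeric(raw[cols["lon"]], errors="coerce"),
        }
    )
    df["timestamp"] = df["timestamp"].dt.tz_localize(None)
    ok = (
        df["timestamp"].notna()
        & df["lat"].between(-90, 90)
        & df["lon"].between(-180, 180)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("read_gps: rejected %d malformed row(s)", n_rejected)
    df = df[ok]
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    dup = df.duplicated(["individual_id", "timestamp"])
    n_dup = int(dup.sum())
    if n_dup:
        logger.warning("read_gps: dropped %d duplicate timestamp(s)", n_dup)
    df = df[~dup].reset_index(drop=True)
    return GpsReadResult(data=df, n_rejected=n_rejected, n_duplicates=n_dup)


def write_gps(data: pd.DataFrame, path, column_map=None) -> None:
    cols = _apply_map(GPS_COLUMNS, column_map)
    out = pd.DataFrame(
        {
            cols["individual_id"]: data["individual_id"],
            cols["timestamp"]: data["timestamp"].dt.strftime(_TS_FORMAT)
            .str[:-3],
            cols["lat"]: data["lat"].map(lambda v: f"{v:.7f}"),
            cols["lon"]: data["lon"].map(lambda v: f"{v:.7f}"),
        }
    )
    out.to_csv(path, index=False)


def read_acc(path, column_map=None) -> AccReadResult:
    """Read a Movebank-style ACC CSV into per-individual burst lists.

    The raw sample string is X Y Z interleaved; a burst whose sample
    count is not divisible by three, or that contains a non-numeric
    token, is rejected (and counted).
    """
    cols = _apply_map(ACC_COLUMNS, column_map)
    raw = pd.read_csv(path, dtype={cols["individual_id"]: str,
                                   cols["raw"]: str})
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"ACC file {path} missing column(s): {missing}")
    result = AccReadResult()
    for row in raw.itertuples(index=False):
        rowd = dict(zip(raw.columns, row))
        rid = rowd[cols["individual_id"]]
        try:
            start = pd.Timestamp(rowd[cols["start"]])
            if start.tzinfo is not None:
                start = start.tz_localize(None)
            hz = float(rowd[cols["hz"]])
            values = np.asarray(str(rowd[cols["raw"]]).split(), dtype=float)
            if len(values) == 0 or len(values) % 3 != 0:
                raise ValueError("sample count not divisible by 3")
            burst = AccBurst(individual_id=rid, start=start, hz=hz,
                             samples=values.reshape(-1, 3))
        except (ValueError, TypeError):
            result.n_rejected += 1
            continue
        result.bursts.setdefault(rid, []).append(burst)
    for bursts in result.bursts.values():
        bursts.sort(key=lambda b: b.start)
    if result.n_rejected:
        logger.warning("read_acc: rejected %d burst(s)", result.n_rejected)
    return result


def write_acc(bursts, path, column_map=None) -> None:
    """Write bursts (iterable or id->list mapping) as Movebank-style CSV."""
    cols = _apply_map(ACC_COLUMNS, column_map)
    if isinstance(bursts, dict):
        bursts = [b for lst in bursts.values() for b in lst]
    rows = []
    for b in sorted(bursts, key=lambda b: (b.individual_id, b.start)):
        raw = " ".join(f"{v:g}" for v in b.samples.reshape(-1))
        rows.append(
            {
                cols["individual_id"]: b.individual_id,
                cols["start"]: b.start.strftime(_TS_FORMAT)[:-3],
                cols["hz"]: f"{b.hz:g}",
                cols["raw"]: raw,
            }
        )
    pd.DataFrame(rows, columns=list(cols.values())).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Individual metadata table.

    Expected columns: ``individual_id, tag_year, region_tagged, sex,
    hatch_rank, n_siblings, nest_lat, nest_lon, exclusion_flags`` with
    flags as a semicolon-separated subset of
    ``not_fledged;eastern_route;device_fault;late_departure``.
    """
    meta = pd.read_csv(path, dtype={"individual_id": str})
    if "exclusion_flags" not in meta.columns:
        meta["exclusion_flags"] = ""
    meta["exclusion_flags"] = meta["exclusion_flags"].fillna("")
    bad = set()
    for flags in meta["exclusion_flags"]:
        bad |= {f for f in str(flags).split(";") if f} - set(EXCLUSION_FLAGS)
    if bad:
        raise ValueError(f"unknown exclusion flag(s): {sorted(bad)}")
    return meta


def apply_cohort_exclusions(metadata: pd.DataFrame):
    """Drop individuals carrying any exclusion flag.

    Returns ``(included_ids, exclusion_counts)``; an individual with
    several flags increments each flag's count but is removed once.
    """
    counts = {f: 0 for f in EXCLUSION_FLAGS}
    included = []
    for row in metadata.itertuples(index=False):
        flags = [f for f in str(getattr(row, "exclusion_flags", "") or
                                "").split(";") if f]
        for f in flags:
            counts[f] += 1
        if not flags:
            included.append(row.individual_id)
    logger.info("cohort filter: %d of %d included (%s)",
                len(included), len(metadata), counts)
    return included, counts
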