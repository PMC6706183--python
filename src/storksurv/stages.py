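"""Life-stage windows and per-stage survival tables.

The juvenile year is split into three stages: postfledging (fledging to
migration departure), migration (departure to 30 September), and winter
(1 October to 28 February of the next calendar year; a leap 29 February
is excluded).  Each stage contributes a survival table with one row per
individual alive at stage entry: time in whole days from stage start to
death (event = 1) or to censoring (tag vanished, or stage end reached);
events on the first stage day get time 0.5 to avoid zero durations.

Stage covariates are the within-window medians of daily ODBA and log
daily distance, plus the baseline traits (sex, hatch rank, number of
siblings, fledging and departure day-of-year, wintering region for the
winter model) and, as carry-over effects, the earlier stages' medians.
The tagging year is carried as the stratification label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["STAGES", "stage_windows", "build_stage_table",
           "overall_km_input"]

STAGES = ("postfledging", "migration", "winter")
MIGRATION_END = (9, 30)  # Sep 30
WINTER_START = (10, 1)
WINTER_END = (2, 28)  # of the following year; Feb 29 excluded


def stage_windows(fledging_date, departure_date, year: int) -> dict:
    """The three stage windows for one individual.

    Returns a dict stage -> (start, end) of Timestamps; ``migration``
    and ``winter`` are absent when departure is unknown, and a
    degenerate window is flagged via the logger.
    """
    year = int(year)
    fledge = pd.Timestamp(fledging_date)
    mig_end = pd.Timestamp(year=year, month=MIGRATION_END[0],
                           day=MIGRATION_END[1])
    win_start = pd.Timestamp(year=year, month=WINTER_START[0],
                             day=WINTER_START[1])
    win_end = pd.Timestamp(year=year + 1, month=WINTER_END[0],
                           day=WINTER_END[1])
    if departure_date is None or pd.isna(departure_date):
        return {"postfledging": (fledge, win_end)}
    depart = pd.Timestamp(departure_date)
    windows = {"postfledging": (fledge, depart)}
    if depart == fledge:
        logger.warning("fledging equals departure; postfledging window "
                       "has zero length")
    if depart > mig_end:
        logger.warning("departure %s after 30 Sep; migration window empty",
                       depart.date())
    else:
        windows["migration"] = (depart, mig_end)
    windows["winter"] = (win_start, win_end)
    return windows


def _median_over(dates, values, start, end):
    sel = (dates >= np.datetime64(start)) & (dates <= np.datetime64(end))
    v = values[sel]
    v = v[np.isfinite(v)]
    return float(np.median(v)) if len(v) else np.nan


def _by_individual(df: pd.DataFrame, col: str) -> dict:
    out = {}
    for ind, g in df.groupby("individual_id", sort=False):
        out[ind] = (g["date"].to_numpy(dtype="datetime64[ns]"),
                    g[col].to_numpy(dtype=float))
    return out


def _stage_medians(feat_by_ind, odba_by_ind, ind, start, end):
    od = odba_by_ind.get(ind)
    ft = feat_by_ind.get(ind)
    return {
        "odba": _median_over(*od, start, end) if od else np.nan,
        "log_dist": _median_over(*ft, start, end) if ft else np.nan,
    }


def build_stage_table(features: pd.DataFrame, odba: pd.DataFrame,
                      fates: pd.DataFrame, phenology: pd.DataFrame,
                      metadata: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Survival table for one life stage.

    Parameters
    ----------
    features : daily displacement features (`daily_features` output)
    odba : daily ODBA series (`daily_odba_series` output)
    fates : fate table (`classify_cohort` output or truth)
    phenology : per-individual fledging/departure/wintering table
    metadata : individual traits incl. ``tag_year``
    stage : one of ``postfledging, migration, winter``
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    fate_ix = fates.set_index("individual_id")
    meta_ix = metadata.set_index("individual_id")
    feat_by_ind = _by_individual(features, "log_displacement")
    odba_by_ind = _by_individual(odba, "odba_median")
    rows = []
    for ph in phenology.itertuples(index=False):
        ind = ph.individual_id
        if ind not in fate_ix.index or ind not in meta_ix.index:
            continue
        if ph.fledging_date is None or pd.isna(ph.fledging_date):
            continue
        meta = meta_ix.loc[ind]
        year = int(meta["tag_year"])
        windows = stage_windows(ph.fledging_date, ph.departure_date, year)
        if stage not in windows:
            continue
        start, end = windows[stage]
        if end <= start:
            continue
        fate = fate_ix.loc[ind]
        death = (pd.Timestamp(fate["death_date"]).normalize()
                 if fate["status"] == "dead" and pd.notna(fate["death_date"])
                 else None)
        last = (pd.Timestamp(fate["last_record_date"]).normalize()
                if pd.notna(fate["last_record_date"]) else None)
        vanished = fate["status"] == "vanished"
        # dead or gone before the stage begins: not at risk in this stage
        if death is not None and death <= start:
            continue
        if vanished and last is not None and last < start:
            continue
        window_days = (end - start).days
        if death is not None and death <= end:
            time = (death - start).days
            event = 1
            row_vanished = False
        else:
            if vanished and last is not None and last < end:
                time = (last - start).days
                row_vanished = True
            else:
                time = window_days
                row_vanished = False
            event = 0
        time = max(float(time), 0.5)  # first-day events get half a day
        # covariate medians run to the day before a death: the death
        # day's (post-mortem) activity is outcome, not predictor
        if event == 1:
            cov_end = start + pd.Timedelta(days=time - 1)
        else:
            cov_end = start + pd.Timedelta(days=time)
        med = _stage_medians(feat_by_ind, odba_by_ind, ind, start,
                             min(cov_end, end))
        row = {
            "individual_id": ind,
            "stage": stage,
            "time_days": time,
            "event": event,
            "vanished": row_vanished,
            "window_days": float(window_days),
            "stratum": year,
            "tag_year": year,
            "sex": meta.get("sex", "unknown"),
            "hatch_rank": meta.get("hatch_rank", np.nan),
            "n_siblings": meta.get("n_siblings", np.nan),
            "fledging_doy": ph.fledging_doy,
            "departure_doy": ph.departure_doy,
            "odba": med["odba"],
            "log_dist": med["log_dist"],
        }
        if stage == "winter":
            row["wintering_region"] = ph.wintering_region
        # carry-over: earlier stages' medians enter later-stage models
        if stage in ("migration", "winter"):
            s, e = windows["postfledging"]
            pf = _stage_medians(feat_by_ind, odba_by_ind, ind, s, e)
            row["odba_postfledging"] = pf["odba"]
            row["log_dist_postfledging"] = pf["log_dist"]
        if stage == "winter" and "migration" in windows:
            s, e = windows["migration"]
            mg = _stage_medians(feat_by_ind, odba_by_ind, ind, s, e)
            row["odba_migration"] = mg["odba"]
            row["log_dist_migration"] = mg["log_dist"]
        rows.append(row)
    return pd.DataFrame(rows)


def overall_km_input(fates: pd.DataFrame, phenology: pd.DataFrame,
                     metadata: pd.DataFrame) -> pd.DataFrame:
    """Times since fledging for the cumulated survival curve.

    Events keep their death day; alive and vanished birds are censored
    (administratively at 28 February ending the first winter).
    """
    meta_ix = metadata.set_index("individual_id")
    fate_ix = fates.set_index("individual_id")
    rows = []
    for ph in phenology.itertuples(index=False):
        ind = ph.individual_id
        if ph.fledging_date is None or pd.isna(ph.fledging_date):
            continue
        if ind not in fate_ix.index or ind not in meta_ix.index:
            continue
        fledge = pd.Timestamp(ph.fledging_date)
        year = int(meta_ix.loc[ind]["tag_year"])
        win_end = pd.Timestamp(year=year + 1, month=WINTER_END[0],
                               day=WINTER_END[1])
        fate = fate_ix.loc[ind]
        if fate["status"] == "dead" and pd.notna(fate["death_date"]):
            t = (pd.Timestamp(fate["death_date"]).normalize() - fledge).days
            event = 1
        elif fate["status"] == "vanished" and pd.notna(
                fate["last_record_date"]):
            t = (min(pd.Timestamp(fate["last_record_date"]).normalize(),
                     win_end) - fledge).days
            event = 0
        else:
            t = (win_end - fledge).days
            event = 0
        rows.append({"individual_id": ind,
                     "time_days": max(float(t), 0.5),
                     "event": event,
                     "vanished": fate["status"] == "vanished",
                     "window_days": float((win_end - fledge).days)})
    return pd.DataFrame(rows)
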