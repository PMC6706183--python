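"""Synthetic juvenile-stork bio-logging cohorts with known ground truth.

The generator emulates the study design every downstream stage assumes:
solar GPS-ACC tags recording 18 hr a day (02:00-20:00 UTC), GPS fixes
at 1 s - 20 min intervals, short tri-axial ACC bursts (1.2-4.1 s at
10.54-33.33 Hz) every 0.5-10 min; a nestling phase at the nest,
post-fledging excursions, a southward migration leg with an
individual-specific stopping latitude (Iberia / North Africa /
Sub-Saharan Africa), and a wintering phase.  Mortality is a daily
Bernoulli draw from a stage-specific baseline hazard scaled by
``exp(beta * (x - center))`` over known covariate values; dead birds
keep transmitting for a while with a stationary GPS cluster (fixes
within 30 m of the death point) and exactly constant ACC bursts, while
"vanished" birds simply stop transmitting with no death signature.

Each individual draws from its own random substream (a hash of its id
mixed with the global seed), so output is byte-identical for identical
(config, seed) regardless of generation order.

Two resolutions are offered: :func:`simulate_cohort` renders full raw
GPS/ACC streams (what the ingest + feature pipeline consumes), and
:func:`simulate_daily` short-cuts straight to daily features and truth
tables, which is what large parameter-recovery simulations need -- the
movement model, hazard draws and truth bookkeeping are shared, only the
within-day rendering is skipped.

Raw ACC units are arbitrary (the tags' calibration is not modelled);
they are scaled so that one unit of daily ODBA corresponds to one unit
of the hazard covariate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AccBurst

__all__ = ["ConfigError", "SimConfig", "SimulatedCohort",
           "simulate_cohort", "simulate_daily", "simulate_acc_burst",
           "write_cohort"]

AXIS_BASELINE = np.array([1800.0, 1900.0, 2200.0])  # raw-unit rest vector
_ODBA_PER_SIGMA = 3.0 * np.sqrt(2.0 / np.pi)  # E[ODBA] per unit noise sd
GIBRALTAR = (36.0, -5.5)
_DEG_KM = 111.19  # km per degree latitude on the 6371-km sphere


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the tagging campaign's sampling scheme and a
    hazard structure whose stage survival matches the juvenile rates
    the three-stage analysis operates on.  ``beta_true`` holds
    log-hazard-ratios per unit of each covariate: daily ODBA acts in
    every stage, log daily distance during migration, and optional
    ``region:NorthAfrica`` / ``region:SubSaharan`` offsets in winter.
    """

    n_individuals: int = 169
    seed: int = 0
    tag_years: tuple = (2013, 2014, 2015, 2016, 2017)
    gps_interval_s: tuple = (1.0, 1200.0)
    acc_burst_s: tuple = (1.2, 4.1)
    acc_hz: tuple = (10.54, 33.33)
    acc_gap_min: tuple = (0.5, 10.0)
    recording_window_utc: tuple = (2, 20)
    fledge_doy_mean_sd: tuple = (196.0, 8.0)
    depart_doy_mean_sd: tuple = (228.8, 11.1)
    region_probs: dict = field(default_factory=lambda: {
        "Europe": 0.5526, "NorthAfrica": 0.2895, "SubSaharan": 0.1579})
    baseline_hazards: dict = field(default_factory=lambda: {
        "postfledging": 0.0043, "migration": 0.0076, "winter": 0.0019})
    beta_true: dict = field(default_factory=lambda: {
        "odba": -0.7, "log_distance": 0.3})
    covariate_centers: dict = field(default_factory=lambda: {
        "odba": 3.0, "log_distance": 4.35})
    vanish_rate: float = 0.0006
    activity_level_range: tuple = (2.0, 4.0)
    post_death_days: int = 14
    daily_odba_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        for name, rng_, lo, hi in (
            ("gps_interval_s", self.gps_interval_s, 1.0, 1200.0),
            ("acc_burst_s", self.acc_burst_s, 1.2, 4.1),
            ("acc_hz", self.acc_hz, 10.54, 33.33),
            ("acc_gap_min", self.acc_gap_min, 0.5, 10.0),
        ):
            a, b = rng_
            if not (a <= b):
                raise ConfigError(f"{name}: empty range {rng_}")
        total = sum(self.region_probs.values())
        if any(p < 0 or p > 1 for p in self.region_probs.values()) or \
                abs(total - 1.0) > 1e-6:
            raise ConfigError("region_probs must lie in [0,1] and sum to 1")
        if any(h < 0 for h in self.baseline_hazards.values()):
            raise ConfigError("baseline hazards must be >= 0")
        if not 0 <= self.vanish_rate <= 1:
            raise ConfigError("vanish_rate must be a daily probability")
        a, b = self.activity_level_range
        if not (0 <= a <= b):
            raise ConfigError("activity_level_range must be nonnegative")


@dataclass
class SimulatedCohort:
    """Raw streams plus metadata and ground truth."""

    gps: pd.DataFrame
    acc: dict  # individual_id -> list[AccBurst]
    metadata: pd.DataFrame
    truth: pd.DataFrame


def _individual_rng(seed: int, individual_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(individual_id.encode())])


def simulate_acc_burst(activity_scale, duration_s, hz, post_death_flag,
                       rng=None, individual_id="sim",
                       start=pd.Timestamp("2015-07-01 02:00:00")) -> AccBurst:
    """One tri-axial burst; sample count = round(duration * hz).

    Post-death bursts are constant at the rest vector on every axis;
    live bursts carry Gaussian dynamic noise whose expected per-sample
    absolute sum equals ``activity_scale`` (the ODBA covariate unit).
    """
    if duration_s <= 0 or hz <= 0:
        raise ConfigError("duration and sampling frequency must be positive")
    n = int(round(duration_s * hz))
    n = max(n, 1)
    if post_death_flag or activity_scale == 0:
        samples = np.tile(AXIS_BASELINE, (n, 1))
    else:
        if rng is None:
            rng = np.random.default_rng()
        sigma = activity_scale / _ODBA_PER_SIGMA
        samples = AXIS_BASELINE + np.round(
            rng.normal(0.0, sigma, size=(n, 3)), 1)
    return AccBurst(individual_id=individual_id, start=start, hz=hz,
                    samples=samples)


# ---------------------------------------------------------------------------
# per-individual daily skeleton


def _simulate_individual(cfg: SimConfig, ind_id: str) -> dict:
    rng = _individual_rng(cfg.seed, ind_id)
    tag_year = int(rng.choice(cfg.tag_years))
    nest_lat = float(rng.uniform(47.0, 53.5))
    nest_lon = float(rng.uniform(7.5, 13.5))
    sex = str(rng.choice(["F", "M"]))
    n_siblings = int(rng.integers(0, 4))
    hatch_rank = int(rng.integers(1, n_siblings + 2))
    region_tagged = f"Region{int(rng.integers(1, 6))}"

    mu, sd = cfg.fledge_doy_mean_sd
    fledge_doy = int(np.clip(round(rng.normal(mu, sd)), 150, 230))
    mu, sd = cfg.depart_doy_mean_sd
    depart_doy = int(np.clip(round(rng.normal(mu, sd)),
                             fledge_doy + 7, 270))
    regions = sorted(cfg.region_probs)
    probs = np.array([cfg.region_probs[r] for r in regions])
    region = str(rng.choice(regions, p=probs / probs.sum()))
    stop_lat = {
        "Europe": rng.uniform(36.5, 43.5),
        "NorthAfrica": rng.uniform(20.5, 35.0),
        "SubSaharan": rng.uniform(12.0, 19.5),
    }[region]
    odba = float(rng.uniform(*cfg.activity_level_range))
    mu_step = rng.normal(np.log(0.7), 0.25)  # log degrees-lat per day

    year_start = pd.Timestamp(year=tag_year, month=1, day=1)
    fledge_date = year_start + pd.Timedelta(days=fledge_doy - 1)
    depart_date = year_start + pd.Timedelta(days=depart_doy - 1)
    deploy_date = fledge_date - pd.Timedelta(days=25)
    study_end = pd.Timestamp(year=tag_year + 1, month=2, day=28)

    # the date grid runs past the study end so that a death on the last
    # study day still gets its post-death signature tail
    dates = pd.date_range(
        deploy_date, study_end + pd.Timedelta(days=cfg.post_death_days),
        freq="D")
    nd = len(dates)
    i_study_end = (study_end - deploy_date).days
    lat = np.full(nd, nest_lat)
    lon = np.full(nd, nest_lon)
    scale_km = np.full(nd, 0.05)
    phase = np.array(["nestling"] * nd, dtype=object)

    i_fledge = (fledge_date - deploy_date).days
    i_depart = (depart_date - deploy_date).days

    # post-fledging: excursions 0.6-5 km from the nest
    for i in range(i_fledge, i_depart):
        r_km = rng.uniform(0.6, 5.0)
        theta = rng.uniform(0, 2 * np.pi)
        lat[i] = nest_lat + (r_km / _DEG_KM) * np.sin(theta)
        lon[i] = nest_lon + (r_km / (_DEG_KM *
                                     np.cos(np.radians(nest_lat)))
                             ) * np.cos(theta)
        scale_km[i] = 1.0
        phase[i] = "postfledging"

    # migration: lat decreases by >= 0.45 deg/day until the stopping
    # latitude; lon tracks toward Gibraltar then on toward West Africa
    cur_lat, cur_lon = nest_lat, nest_lon
    i = i_depart
    arrival_idx = None
    while i < nd:
        step = float(np.exp(rng.normal(mu_step, 0.2)))
        step = max(step, 0.45)
        nxt = cur_lat - step
        if nxt <= stop_lat:
            nxt = stop_lat
        if cur_lat > GIBRALTAR[0]:
            frac = np.clip((nest_lat - nxt) / max(nest_lat - GIBRALTAR[0],
                                                  1e-9), 0, 1)
            cur_lon = nest_lon + frac * (GIBRALTAR[1] - nest_lon)
        else:
            frac = np.clip((GIBRALTAR[0] - nxt) / max(GIBRALTAR[0] - 12.0,
                                                      1e-9), 0, 1)
            cur_lon = GIBRALTAR[1] + frac * (-13.0 - GIBRALTAR[1])
        cur_lat = nxt
        lat[i] = cur_lat
        lon[i] = cur_lon + rng.normal(0, 0.02)
        scale_km[i] = 5.0
        phase[i] = "travel"
        if cur_lat <= stop_lat:
            arrival_idx = i
            break
        i += 1
    # wintering: local movements around the terminal site
    w0 = (arrival_idx + 1) if arrival_idx is not None else nd
    for i in range(w0, nd):
        lat[i] = stop_lat + rng.normal(0, 0.02)
        lon[i] = lon[w0 - 1] + rng.normal(0, 0.02)
        scale_km[i] = 1.0
        phase[i] = "winter_site"

    # realised movement covariate: log median daily step (km) over the
    # actual travel leg, which is what "migration distance" means here
    mig_end = pd.Timestamp(year=tag_year, month=9, day=30)
    step_km = _DEG_KM * np.sqrt(
        np.diff(lat) ** 2
        + (np.diff(lon) * np.cos(np.radians(lat[1:]))) ** 2)
    in_travel = phase[1:] == "travel"
    if in_travel.any():
        log_distance = float(np.log(max(np.median(step_km[in_travel]),
                                        1e-3)))
    else:
        log_distance = np.nan

    # daily hazard by stage window
    win_start = pd.Timestamp(year=tag_year, month=10, day=1)
    doy_dates = dates
    p_death = np.zeros(nd)
    centers = cfg.covariate_centers
    beta = cfg.beta_true
    for i, d in enumerate(doy_dates):
        if d < fledge_date or d > study_end:
            continue
        if d < depart_date:
            stage = "postfledging"
        elif d <= mig_end:
            stage = "migration"
        elif d >= win_start:
            stage = "winter"
        else:
            continue
        lam = cfg.baseline_hazards.get(stage, 0.0)
        if lam <= 0:
            continue
        lp = beta.get("odba", 0.0) * (odba - centers.get("odba", 0.0))
        if stage == "migration" and np.isfinite(log_distance):
            lp += beta.get("log_distance", 0.0) * (
                log_distance - centers.get("log_distance", 0.0))
        if stage == "winter" and region != "Europe":
            lp += beta.get(f"region:{region}", 0.0)
        p_death[i] = 1.0 - np.exp(-lam * np.exp(lp))

    u_death = rng.random(nd)
    u_vanish = rng.random(nd)
    death_idx = np.flatnonzero(u_death < p_death)
    vanish_idx = np.flatnonzero(
        (u_vanish < cfg.vanish_rate)
        & (np.arange(nd) <= i_study_end))
    death_i = int(death_idx[0]) if len(death_idx) else None
    vanish_i = int(vanish_idx[0]) if len(vanish_idx) else None

    if vanish_i is not None and (death_i is None or vanish_i < death_i):
        fate, death_i = "vanished", None
        last_i = vanish_i
        vanish_date = dates[vanish_i]
        death_date = None
    elif death_i is not None:
        fate = "dead"
        vanish_date = None
        death_date = dates[death_i]
        last_i = min(death_i + cfg.post_death_days, nd - 1)
    else:
        fate = "alive"
        vanish_date = death_date = None
        last_i = i_study_end

    dead_flag = np.zeros(nd, dtype=bool)
    if death_i is not None:
        dead_flag[death_i:] = True
        lat[death_i:] = lat[death_i]
        lon[death_i:] = lon[death_i]
        scale_km[death_i:] = 0.02
        phase[death_i:] = "dead"

    keep = slice(0, last_i + 1)
    return {
        "individual_id": ind_id, "tag_year": tag_year,
        "nest_lat": nest_lat, "nest_lon": nest_lon, "sex": sex,
        "hatch_rank": hatch_rank, "n_siblings": n_siblings,
        "region_tagged": region_tagged,
        "fledge_date": fledge_date, "fledge_doy": fledge_doy,
        "depart_date": depart_date, "depart_doy": depart_doy,
        "region": region, "stop_lat": float(stop_lat),
        "odba": odba, "log_distance": log_distance,
        "fate": fate, "death_date": death_date, "vanish_date": vanish_date,
        "last_record_date": dates[last_i], "study_end": study_end,
        "dates": dates[keep], "lat": lat[keep], "lon": lon[keep],
        "scale_km": scale_km[keep], "dead_flag": dead_flag[keep],
        "rng": rng,
    }


# ---------------------------------------------------------------------------
# rendering


def _render_gps_days(ind: dict, cfg: SimConfig, rng) -> pd.DataFrame:
    h0, h1 = cfg.recording_window_utc
    window_s = (h1 - h0) * 3600.0
    lo, hi = cfg.gps_interval_s
    frames = []
    for day, la, lo_, sc, dead in zip(ind["dates"], ind["lat"], ind["lon"],
                                      ind["scale_km"], ind["dead_flag"]):
        mean_gap = 0.5 * (lo + hi)
        n_max = int(window_s / max(mean_gap, 1.0) * 3) + 8
        gaps = rng.uniform(lo, hi, size=n_max)
        t = np.cumsum(gaps)
        t = t[t < window_s - 1.0]
        t = np.concatenate([[rng.uniform(0, min(30.0, lo + 1.0))], t])
        nfix = len(t)
        if dead:
            r = rng.uniform(0, 0.025, nfix)  # within 25 m of death point
        else:
            r = rng.uniform(0, sc, nfix)
        theta = rng.uniform(0, 2 * np.pi, nfix)
        dlat = (r / _DEG_KM) * np.sin(theta)
        dlon = (r / (_DEG_KM * np.cos(np.radians(la)))) * np.cos(theta)
        dlat[0] = dlon[0] = 0.0  # first fix sits on the daily anchor
        ts = (day + pd.Timedelta(hours=h0)
              + pd.to_timedelta(np.round(t * 1000).astype("int64"),
                                unit="ms"))
        frames.append(pd.DataFrame({
            "individual_id": ind["individual_id"], "timestamp": ts,
            "lat": la + dlat, "lon": lo_ + dlon,
        }))
    return pd.concat(frames, ignore_index=True)


def _render_acc_days(ind: dict, cfg: SimConfig, rng) -> list:
    h0, h1 = cfg.recording_window_utc
    window_s = (h1 - h0) * 3600.0
    g0, g1 = (60.0 * g for g in cfg.acc_gap_min)
    bursts = []
    for day, dead in zip(ind["dates"], ind["dead_flag"]):
        t = 0.0
        day_scale = ind["odba"] * float(np.exp(rng.normal(0.0, 0.03)))
        while True:
            t += rng.uniform(g0, g1)
            dur = rng.uniform(*cfg.acc_burst_s)
            if t + dur >= window_s:
                break
            hz = round(rng.uniform(*cfg.acc_hz), 2)
            start = (day + pd.Timedelta(hours=h0)
                     + pd.Timedelta(milliseconds=int(round(t * 1000))))
            bursts.append(simulate_acc_burst(
                day_scale, dur, hz, bool(dead), rng=rng,
                individual_id=ind["individual_id"], start=start))
    return bursts


# ---------------------------------------------------------------------------
# cohort-level API


def _individual_ids(cfg: SimConfig) -> list:
    return [f"stork{i:04d}" for i in range(1, cfg.n_individuals + 1)]


def _meta_row(ind: dict) -> dict:
    return {
        "individual_id": ind["individual_id"],
        "tag_year": ind["tag_year"],
        "region_tagged": ind["region_tagged"],
        "sex": ind["sex"], "hatch_rank": ind["hatch_rank"],
        "n_siblings": ind["n_siblings"],
        "nest_lat": round(ind["nest_lat"], 7),
        "nest_lon": round(ind["nest_lon"], 7),
        "exclusion_flags": "",
    }


def _truth_row(ind: dict) -> dict:
    return {
        "individual_id": ind["individual_id"],
        "true_fledge_doy": ind["fledge_doy"],
        "true_depart_doy": ind["depart_doy"],
        "true_region": ind["region"],
        "true_fate": ind["fate"],
        "true_death_date": ind["death_date"],
        "true_vanish_date": ind["vanish_date"],
        "last_record_date": ind["last_record_date"],
        "study_end": ind["study_end"],
        "stop_lat": ind["stop_lat"],
        "odba": ind["odba"],
        "log_distance": ind["log_distance"],
        "tag_year": ind["tag_year"],
    }


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Full-resolution cohort: raw GPS/ACC streams, metadata, truth."""
    gps_frames, acc, meta_rows, truth_rows = [], {}, [], []
    for ind_id in _individual_ids(config):
        ind = _simulate_individual(config, ind_id)
        rng = ind["rng"]
        gps_frames.append(_render_gps_days(ind, config, rng))
        acc[ind_id] = _render_acc_days(ind, config, rng)
        meta_rows.append(_meta_row(ind))
        truth_rows.append(_truth_row(ind))
    gps = (pd.concat(gps_frames, ignore_index=True) if gps_frames
           else pd.DataFrame(columns=["individual_id", "timestamp",
                                      "lat", "lon"]))
    return SimulatedCohort(gps=gps, acc=acc,
                           metadata=pd.DataFrame(meta_rows),
                           truth=pd.DataFrame(truth_rows))


def simulate_daily(config: SimConfig):
    """Daily-resolution cohort for large simulation studies.

    Returns ``(features, odba, fates, phenology, metadata, truth)``
    where ``features``/``odba`` mimic the outputs of the GPS/ACC
    feature pipeline, and ``fates``/``phenology`` are truth-valued (as
    if detection were perfect), letting survival-model studies run
    without raw-stream rendering.
    """
    feat_frames, odba_rows, fate_rows, ph_rows = [], [], [], []
    meta_rows, truth_rows = [], []
    for ind_id in _individual_ids(config):
        ind = _simulate_individual(config, ind_id)
        rng = ind["rng"]
        dates = ind["dates"]
        lat, lon = ind["lat"], ind["lon"]
        disp = np.concatenate([
            [np.nan],
            _DEG_KM * np.sqrt(
                np.diff(lat) ** 2
                + (np.diff(lon) * np.cos(np.radians(lat[1:]))) ** 2),
        ])
        feat_frames.append(pd.DataFrame({
            "individual_id": ind_id, "date": dates,
            "doy": dates.dayofyear,
            "first_fix_lat": lat, "first_fix_lon": lon,
            "displacement_km": disp,
            "log_displacement": np.log(np.maximum(disp, 1e-3)),
        }))
        alive_days = ~ind["dead_flag"]
        odba_vals = np.maximum(
            ind["odba"] + rng.normal(0, config.daily_odba_noise_sd,
                                     len(dates)), 0.0)
        odba_vals[~alive_days] = 0.0
        odba_rows.append(pd.DataFrame({
            "individual_id": ind_id, "date": dates,
            "odba_median": odba_vals,
            "n_bursts": 100,
        }))
        fate_rows.append({
            "individual_id": ind_id, "status": ind["fate"],
            "death_date": ind["death_date"],
            "criterion": "none" if ind["fate"] != "dead" else "truth",
            "last_record_date": ind["last_record_date"],
        })
        ph_rows.append({
            "individual_id": ind_id,
            "fledging_date": ind["fledge_date"],
            "fledging_doy": ind["fledge_doy"],
            "departure_date": ind["depart_date"],
            "departure_doy": ind["depart_doy"],
            "wintering_region": ind["region"],
            "southernmost_lat": ind["stop_lat"],
        })
        meta_rows.append(_meta_row(ind))
        truth_rows.append(_truth_row(ind))
    features = pd.concat(feat_frames, ignore_index=True)
    odba = pd.concat(odba_rows, ignore_index=True)
    return (features, odba, pd.DataFrame(fate_rows), pd.DataFrame(ph_rows),
            pd.DataFrame(meta_rows), pd.DataFrame(truth_rows))


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write Movebank-style gps.csv / acc.csv plus meta.csv, truth.csv."""
    from pathlib import Path

    from .io import write_acc, write_gps

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in ("gps", "acc", "meta", "truth")}
    write_gps(cohort.gps, paths["gps"])
    write_acc(cohort.acc, paths["acc"])
    cohort.metadata.to_csv(paths["meta"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    return paths
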