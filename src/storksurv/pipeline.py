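"""End-to-end orchestration: streams -> features -> fates -> stages ->
survival models -> diagnostics -> report bundle.

The pipeline is deterministic given (config, seed): every intermediate
table is written as CSV and the headline numbers as a summary JSON, so
a rerun with the same configuration reproduces the bundle byte for
byte.  One structured log line per stage records counts in and out,
keeping cohort attrition auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stages as stages_mod
from .cox import CoxPH
from .diagnostics import censoring_sensitivity, schoenfeld_test, welch_t
from .fate import classify_cohort
from .km import KaplanMeier
from .odba import daily_odba_series
from .simulate import SimConfig, simulate_cohort, write_cohort
from .tracks import compute_phenology, daily_features

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort",
           "round_pct"]

DEFAULT_TERMS = {
    "postfledging": ["odba", "log_dist", "rcs(fledging_doy)", "C(sex)",
                     "hatch_rank", "n_siblings"],
    "migration": ["odba", "log_dist", "rcs(fledging_doy)",
                  "rcs(departure_doy)", "C(sex)", "hatch_rank",
                  "n_siblings", "odba_postfledging"],
    "winter": ["odba", "log_dist", "C(wintering_region)",
               "rcs(fledging_doy)", "C(sex)", "hatch_rank", "n_siblings",
               "odba_migration", "log_dist_migration"],
}


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (or a simulate block), model
    settings, and the named analysis thresholds."""

    simulate: SimConfig | None = None
    gps_path: str | None = None
    acc_path: str | None = None
    meta_path: str | None = None
    structure_path: str | None = None
    overrides_path: str | None = None  # field-confirmed deaths
    out_dir: str = "lifeline_out"
    terms: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                 DEFAULT_TERMS.items()})
    use_enet: bool = True
    alpha: float = 0.5
    cv_folds: int = 10
    seed: int = 0
    flat_eps: float = 1.0
    write_streams: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg


def round_pct(count: float, total: float) -> float:
    """Percentage rounded to two decimals, half-up."""
    if total == 0:
        raise ZeroDivisionError("empty denominator")
    pct = Decimal(str(count)) * 100 / Decimal(str(total))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_cohort(fates: pd.DataFrame, phenology: pd.DataFrame) -> dict:
    """Fate counts and wintering-region shares.

    Shares are computed over individuals with an assigned wintering
    region and rounded to two decimals (half-up).
    """
    counts = fates["status"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("alive", "dead",
                                                 "vanished")}
    crit = (fates.loc[fates["status"] == "dead", "criterion"]
            .value_counts().to_dict())
    regions = phenology["wintering_region"].dropna()
    region_counts = regions.value_counts().to_dict()
    total = int(len(regions))
    if total:
        shares = {r: round_pct(c, total) for r, c in
                  sorted(region_counts.items())}
    else:
        shares = None
        logger.warning("no individuals with an assigned wintering region")
    return {
        "cohort_size": int(len(fates)),
        "fate_counts": counts,
        "death_criterion_counts": {k: int(v) for k, v in
                                   sorted(crit.items())},
        "wintering_region_counts": {k: int(v) for k, v in
                                    sorted(region_counts.items())},
        "wintering_region_pct": shares,
    }


def _km_summary(km_results) -> dict:
    tab = km_results.table
    return {
        "n": km_results.n,
        "n_events": km_results.n_events_total,
        "final_survival": float(tab["surv"].iloc[-1]) if len(tab) else 1.0,
        "median_survival_days": km_results.median_survival_time,
    }


def _fit_stage_model(table: pd.DataFrame, terms, cfg: PipelineConfig):
    """Elastic-net selection + unpenalised refit (or plain fit)."""
    usable = [t for t in terms if _term_usable(table, t)]
    if not usable or int(table["event"].sum()) < 2:
        return None, None
    model = CoxPH(table, usable, strata_col="stratum")
    if not cfg.use_enet:
        return model.fit(), None
    path = model.fit_regularized(alpha=cfg.alpha, cv_folds=cfg.cv_folds,
                                 seed=cfg.seed)
    return path.refit(), path


def _term_usable(table, term) -> bool:
    import re

    for part in term.split(":"):
        m = re.match(r"^(?:rcs|C)\(\s*([^,()\s]+)", part.strip())
        col = m.group(1) if m else part.strip()
        if col not in table.columns:
            return False
        v = table[col].dropna()
        if v.nunique() < 2:
            return False
    return True


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns the summary dict (also written
    to ``out_dir/summary.json`` along with every intermediate CSV)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        gps, acc, meta = cohort.gps, cohort.acc, cohort.metadata
        cohort.truth.to_csv(out / "truth.csv", index=False)
        if config.write_streams:
            write_cohort(cohort, out / "streams")
    else:
        from .io import read_acc, read_gps, read_metadata

        gps = read_gps(config.gps_path).data
        acc = read_acc(config.acc_path).bursts
        meta = read_metadata(config.meta_path)

    from .io import apply_cohort_exclusions

    included, excl_counts = apply_cohort_exclusions(meta)
    gps = gps[gps["individual_id"].isin(included)]
    acc = {k: v for k, v in acc.items() if k in included}
    meta = meta[meta["individual_id"].isin(included)].reset_index(drop=True)
    logger.info("pipeline: %d individuals after exclusions (%s)",
                len(included), excl_counts)

    missing_acc = set(gps["individual_id"].unique()) - set(acc)
    if missing_acc:
        logger.warning("ACC stream missing for %d individual(s); "
                       "proceeding with GPS only", len(missing_acc))

    features = daily_features(gps)
    odba = daily_odba_series(acc)
    phenology = compute_phenology(gps, meta)
    features.to_csv(out / "daily_features.csv", index=False)
    odba.to_csv(out / "daily_odba.csv", index=False)
    phenology.to_csv(out / "phenology.csv", index=False)

    structures = None
    if config.structure_path:
        structures = pd.read_csv(config.structure_path)
    overrides = None
    if config.overrides_path:
        ov = pd.read_csv(config.overrides_path,
                         dtype={"individual_id": str})
        overrides = dict(zip(ov["individual_id"],
                             pd.to_datetime(ov["death_date"])))
    meta_ix = meta.set_index("individual_id")
    study_end = {
        i: pd.Timestamp(year=int(meta_ix.loc[i, "tag_year"]) + 1,
                        month=2, day=28)
        for i in meta_ix.index
    }
    starts = {r.individual_id: r.fledging_date
              for r in phenology.itertuples()}
    fates = classify_cohort(gps, acc, structures, study_end,
                            overrides=overrides, flat_eps=config.flat_eps,
                            start_dates=starts)
    fates.to_csv(out / "fates.csv", index=False)

    summary = {"exclusions": excl_counts,
               "cohort": summarize_cohort(fates, phenology)}

    overall = stages_mod.overall_km_input(fates, phenology, meta)
    if len(overall):
        km_overall = KaplanMeier.from_dataframe(overall).fit()
        km_overall.table.to_csv(out / "km_overall.csv", index=False)
        summary["km_overall"] = _km_summary(km_overall)

    stage_tables = {}
    summary["stages"] = {}
    for stage in stages_mod.STAGES:
        table = stages_mod.build_stage_table(features, odba, fates,
                                             phenology, meta, stage)
        stage_tables[stage] = table
        table.to_csv(out / f"stage_{stage}.csv", index=False)
        entry = {"n": int(len(table)),
                 "n_events": int(table["event"].sum()) if len(table) else 0,
                 "n_vanished": int(table["vanished"].sum())
                 if len(table) else 0}
        if len(table):
            km = KaplanMeier.from_dataframe(table).fit()
            km.table.to_csv(out / f"km_{stage}.csv", index=False)
            entry["km"] = _km_summary(km)
            fit, path = _fit_stage_model(table, config.terms[stage], config)
            if fit is not None and fit.df_model > 0:
                report = fit.to_report()
                if path is not None:
                    report["selected_lambda"] = path.selected_lambda
                    report["selected_terms"] = path.selected_terms
                try:
                    ph = schoenfeld_test(fit)
                    report["ph_global_p"] = ph.global_p
                except ValueError:
                    pass
                (out / f"model_{stage}.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True,
                               default=str))
                entry["model"] = {"df": report["df"],
                                  "lr_statistic": report["lr_statistic"],
                                  "lr_pvalue": report["lr_pvalue"],
                                  "r_squared": report["r_squared"]}
                sens = censoring_sensitivity(table)
                (out / f"sensitivity_{stage}.json").write_text(
                    json.dumps(sens.to_dict(), indent=2, sort_keys=True,
                               default=str))
        summary["stages"][stage] = entry

    # vanished-bird comparisons: did birds that vanished travel farther?
    mig = stage_tables.get("migration")
    if mig is not None and len(mig):
        groups = {
            "vanished": mig.loc[mig["vanished"], "log_dist"].dropna(),
            "alive": mig.loc[(mig["event"] == 0) & ~mig["vanished"],
                             "log_dist"].dropna(),
            "dead": mig.loc[mig["event"] == 1, "log_dist"].dropna(),
        }
        welch = {}
        for a, b in (("alive", "vanished"), ("dead", "vanished")):
            if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                t, df, p = welch_t(groups[a], groups[b])
                welch[f"{a}_vs_vanished"] = {"t": t, "df": df, "p": p}
        if welch:
            summary["welch_log_distance"] = welch

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
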