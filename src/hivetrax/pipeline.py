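"""End-to-end orchestration: ingest -> flights -> survival -> stats -> GLMM.

``run_analysis`` reads a study (registration log, roster, weather, light),
runs every analysis stage and writes each result as a plain CSV table plus
a human-readable summary, so the full report is auditable intermediate by
intermediate.  A stage failure is recorded in ``manifest.json`` and later
stages that do not depend on it still run; the run is deterministic given
the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classic_stats, events_io, flights as flights_mod, survival, zinb_glmm

__all__ = ["RunConfig", "run_analysis", "run_demo", "checksum_report"]


@dataclass
class RunConfig:
    data_dir: Path
    out_dir: Path
    window: tuple[date, date] = (date(2022, 5, 2), date(2022, 8, 31))
    utc_offset_hours: float = 2.0
    seed: int = 0
    glmm_candidates: str = "default"  # "default" | "final-only" | "none"
    max_flight_gap_hours: float = 24.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            data_dir=Path(raw["data_dir"]),
            out_dir=Path(raw["out_dir"]),
            window=(date.fromisoformat(str(raw.get("window_start", "2022-05-02"))),
                    date.fromisoformat(str(raw.get("window_end", "2022-08-31")))),
            utc_offset_hours=float(raw.get("utc_offset_hours", 2.0)),
            seed=int(raw.get("seed", 0)),
            glmm_candidates=str(raw.get("glmm_candidates", "default")),
            max_flight_gap_hours=float(raw.get("max_flight_gap_hours", 24.0)),
        )

    def validate(self) -> None:
        for name in ("registrations.csv", "roster.csv", "weather_5min.csv",
                     "light_hourly.csv"):
            p = Path(self.data_dir) / name
            if not p.exists():
                raise FileNotFoundError(f"missing input file: {p}")


def _write(df: pd.DataFrame, out: Path, name: str) -> None:
    df.to_csv(out / name, index=False)


def run_analysis(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "window": [str(w) for w in config.window]}
    summary_lines: list[str] = []

    regs, parse_errors = events_io.parse_registrations(Path(config.data_dir) / "registrations.csv")
    roster = events_io.parse_roster(Path(config.data_dir) / "roster.csv")
    weather = pd.read_csv(Path(config.data_dir) / "weather_5min.csv")
    light = pd.read_csv(Path(config.data_dir) / "light_hourly.csv")
    by_tag = {b.tag_id: b for b in roster}
    manifest["n_registrations"] = len(regs)
    manifest["n_parse_errors"] = len(parse_errors)
    summary_lines.append(f"registrations parsed: {len(regs)} ({len(parse_errors)} malformed lines)")

    def stage(name: str):
        def wrap(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:  # pragma: no cover - failure path
                manifest["stages"][name] = f"failed: {exc}"
                (out / f"failure_{name}.txt").write_text(traceback.format_exc())
            return None
        return wrap

    records = survival.life_history_table(regs, roster, config.utc_offset_hours)
    shared: dict = {"records": records}

    @stage("cohort_summary")
    def _cohort():
        tab = survival.cohort_summary(records, roster, group_keys=("individual_type",))
        tab2 = survival.cohort_summary(
            records, roster, group_keys=("individual_type", "subspecies", "cohort")
        )
        _write(tab, out, "cohort_summary.csv")
        _write(tab2, out, "cohort_summary_by_group.csv")
        lh = pd.DataFrame([r.__dict__ for r in records])
        _write(lh, out, "life_history.csv")
        for _, row in tab.iterrows():
            summary_lines.append(
                f"{row['individual_type']}s: {row['n_registered']}/{row['n_tagged']} registered "
                f"({row['percent_registered']}%), mean lifespan {row['mean_lifespan']:.1f} d "
                f"(max {row['max_lifespan']})"
            )

    @stage("survival")
    def _survival():
        groups = {}
        for r in records:
            bee = by_tag[r.tag_id]
            groups.setdefault((bee.individual_type, bee.cohort), []).append(
                (float(r.lifespan_days), r.event)
            )
            groups.setdefault((bee.individual_type, bee.subspecies, bee.cohort), []).append(
                (float(r.lifespan_days), r.event)
            )
        km_rows = []
        for key, data in sorted(groups.items()):
            curve = survival.km_estimate(data)
            label = ":".join(key)
            for t, nr, d, s, v in zip(curve.t, curve.n_risk, curve.d,
                                      curve.survival, curve.var):
                km_rows.append({"group": label, "t": t, "n_risk": nr, "d": d,
                                "survival": s, "var": v})
        _write(pd.DataFrame(km_rows), out, "km_curves.csv")

        comparisons = []
        def compare(name, g1, g2):
            if g1 in groups and g2 in groups and groups[g1] and groups[g2]:
                chi2, df, p = survival.logrank_test([groups[g1], groups[g2]])
                comparisons.append({"comparison": name, "chisq": chi2, "df": df, "p": p,
                                    "n1": len(groups[g1]), "n2": len(groups[g2])})
                summary_lines.append(f"log-rank {name}: Chisq = {chi2:.1f}, p = {p:.3g}")
        compare("drone spring vs summer", ("drone", "spring"), ("drone", "summer"))
        compare("drone Buck vs Mel (summer)", ("drone", "Buck", "summer"),
                ("drone", "Mel", "summer"))
        compare("worker spring vs summer", ("worker", "spring"), ("worker", "summer"))
        drones = [(float(r.lifespan_days), r.event) for r in records
                  if by_tag[r.tag_id].individual_type == "drone"]
        workers = [(float(r.lifespan_days), r.event) for r in records
                   if by_tag[r.tag_id].individual_type == "worker"]
        if drones and workers:
            chi2, df, p = survival.logrank_test([drones, workers])
            comparisons.append({"comparison": "drone vs worker", "chisq": chi2, "df": df,
                                "p": p, "n1": len(drones), "n2": len(workers)})
            summary_lines.append(f"log-rank drone vs worker: Chisq = {chi2:.1f}, p = {p:.3g}")
        _write(pd.DataFrame(comparisons), out, "logrank.csv")

    @stage("first_activity")
    def _first_activity():
        rows = []
        def mw(name, xs, ys):
            if len(xs) and len(ys):
                res = classic_stats.mann_whitney(xs, ys)
                rows.append({"comparison": name, "W": res.W, "p": res.p_value,
                             "method": res.method, "n1": len(xs), "n2": len(ys)})
                summary_lines.append(f"Mann-Whitney {name}: W = {res.W:.1f}, p = {res.p_value:.3g}")
        for itype in ("drone", "worker"):
            spring = [r.first_activity_age_days for r in records
                      if by_tag[r.tag_id].individual_type == itype
                      and by_tag[r.tag_id].cohort == "spring"]
            summer = [r.first_activity_age_days for r in records
                      if by_tag[r.tag_id].individual_type == itype
                      and by_tag[r.tag_id].cohort == "summer"]
            mw(f"{itype} first activity spring vs summer", spring, summer)
            buck = [r.first_activity_age_days for r in records
                    if by_tag[r.tag_id].individual_type == itype
                    and by_tag[r.tag_id].cohort == "summer"
                    and by_tag[r.tag_id].subspecies == "Buck"]
            mel = [r.first_activity_age_days for r in records
                   if by_tag[r.tag_id].individual_type == itype
                   and by_tag[r.tag_id].cohort == "summer"
                   and by_tag[r.tag_id].subspecies == "Mel"]
            mw(f"{itype} first activity Buck vs Mel (summer)", buck, mel)
        _write(pd.DataFrame(rows), out, "first_activity_tests.csv")

    # flights
    all_flights: list = []
    @stage("flights")
    def _flights():
        per_tag: dict[str, list] = {}
        for r in regs:
            if r.tag_id in by_tag:
                per_tag.setdefault(r.tag_id, []).append(r)
        for tag, rr in sorted(per_tag.items()):
            rr.sort(key=lambda x: x.timestamp_utc)
            fl, _ = flights_mod.reconstruct_flights(
                rr, by_tag[tag], config.max_flight_gap_hours, config.utc_offset_hours
            )
            all_flights.extend(fl)
        fdf = flights_mod.flights_frame(all_flights)
        _write(fdf, out, "flights.csv")
        cat = flights_mod.flight_summary(
            all_flights, ("individual_type", "cohort", "category"), by_tag
        )
        _write(cat, out, "flight_categories.csv")
        # age vs duration correlation per type and cohort
        rows = []
        for (itype, cohort), grp in _flight_groups(all_flights, by_tag):
            ages = [ (f.departure_time.date() - by_tag[f.tag_id].tagging_date).days
                     for f in grp]
            durs = [f.duration for f in grp]
            if len(grp) >= 3:
                rho = classic_stats.spearman_rho(ages, durs)
                rows.append({"individual_type": itype, "cohort": cohort,
                             "n_flights": len(grp), "rho_age_duration": rho})
        _write(pd.DataFrame(rows), out, "flight_age_duration.csv")
        summary_lines.append(f"flights reconstructed: {len(all_flights)}")

    # hourly counts (drones and workers)
    tables: dict[str, pd.DataFrame] = {}
    @stage("hourly_counts")
    def _counts():
        for itype in ("drone", "worker"):
            tab, report = events_io.build_hourly_counts(
                regs, roster, weather, light, config.window,
                individual_type=itype, utc_offset_hours=config.utc_offset_hours,
            )
            tables[itype] = tab
            tab.to_csv(out / f"hourly_counts_{itype}.csv", index=False)
            manifest[f"count_report_{itype}"] = {
                k: v for k, v in report.__dict__.items() if not isinstance(v, list)
            }

    @stage("diurnal")
    def _diurnal():
        shares = []
        peaks = []
        for itype, tab in tables.items():
            t = tab.dropna(subset=["count"])
            for season, sub in t.groupby("season"):
                tot = sub["count"].sum()
                if tot == 0:
                    continue
                for iv in events_io.INTERVALS:
                    n = sub.loc[sub["interval"] == iv, "count"].sum()
                    shares.append({"individual_type": itype, "season": season,
                                   "interval": iv, "n": int(n), "share": n / tot})
                by_hour = sub.groupby("hour")["count"].sum()
                peaks.append({"individual_type": itype, "season": season,
                              "peak_hour": int(by_hour.idxmax()),
                              "share": float(by_hour.max() / tot)})
        _write(pd.DataFrame(shares), out, "diurnal_shares.csv")
        _write(pd.DataFrame(peaks), out, "peak_hours.csv")

        # Type-II ANOVA on log(count+1) aggregated per hive x date x interval
        drone = tables.get("drone", pd.DataFrame()).dropna(subset=["count"])
        if len(drone):
            agg = drone.groupby(["hive_id", "date", "interval", "subspecies"],
                                as_index=False)["count"].sum()
            res = classic_stats.type2_anova(
                agg["count"], agg["subspecies"], agg["interval"], transform="log1p"
            )
            _write(res.table.assign(model="drone: subspecies x interval"),
                   out, "anova_interval.csv")
            _write(res.tukey, out, "tukey_interval.csv")
        both = pd.concat(
            [tab.dropna(subset=["count"]).assign(individual_type=itype)
             for itype, tab in tables.items()],
            ignore_index=True,
        )
        if len(both):
            agg = both.groupby(["hive_id", "date", "interval", "individual_type"],
                               as_index=False)["count"].sum()
            res = classic_stats.type2_anova(
                agg["count"], agg["individual_type"], agg["interval"], transform="log1p"
            )
            _write(res.table.assign(model="type x interval"), out, "anova_type_interval.csv")
            _write(res.tukey, out, "tukey_type_interval.csv")

    @stage("weather")
    def _weather():
        per_day_all = []
        summ_all = []
        for itype, tab in tables.items():
            for ss, sub in tab.groupby("subspecies"):
                per_day, summ = classic_stats.daily_weather_correlations(sub)
                per_day_all.append(per_day.assign(individual_type=itype, subspecies=ss))
                summ_all.append(summ.assign(individual_type=itype, subspecies=ss))
        _write(pd.concat(per_day_all, ignore_index=True), out, "weather_correlations_daily.csv")
        summ = pd.concat(summ_all, ignore_index=True)
        _write(summ, out, "weather_correlations_summary.csv")
        for _, row in summ[summ["individual_type"] == "drone"].iterrows():
            summary_lines.append(
                f"drone {row['subspecies']} daily rho({row['variable']}): "
                f"median {row['median_rho']:.2f}"
            )

    @stage("glmm")
    def _glmm():
        if config.glmm_candidates == "none":
            return
        rows = tables["drone"]
        v = zinb_glmm.vif(rows)
        _write(v.rename("vif").reset_index().rename(columns={"index": "covariate"}),
               out, "glmm_vif.csv")
        if config.glmm_candidates == "final-only":
            candidates = [zinb_glmm.DRONE_FINAL]
        else:
            candidates = zinb_glmm.default_candidates()
        aic_tab, chosen, fits = zinb_glmm.select_model(rows, candidates, seed=config.seed)
        _write(aic_tab, out, "glmm_aic.csv")
        design = zinb_glmm.build_design(rows, chosen)
        best = zinb_glmm.fit(design, seed=config.seed)
        tables_inf = zinb_glmm.infer(best)
        _write(tables_inf["coefficients"], out, "glmm_coefficients.csv")
        _write(tables_inf["deviance"], out, "glmm_deviance.csv")
        _write(tables_inf["effects"], out, "glmm_effects.csv")
        summary_lines.append(
            f"GLMM chosen model: {chosen.name} (AIC {best.aic:.1f}); "
            f"zero-inflation hour slope {best.gamma:.3f}; phi {best.phi:.2f}"
        )
        manifest["glmm_chosen"] = chosen.name

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _flight_groups(all_flights, by_tag):
    groups: dict[tuple[str, str], list] = {}
    for f in all_flights:
        bee = by_tag[f.tag_id]
        groups.setdefault((bee.individual_type, bee.cohort), []).append(f)
    return sorted(groups.items())


def checksum_report(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every CSV/txt report file (for determinism checks)."""
    out = Path(out_dir)
    sums = {}
    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.txt")):
        sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums


def run_demo(
    work_dir: str | Path,
    seed: int = 42,
    window: tuple[date, date] = (date(2022, 5, 2), date(2022, 7, 15)),
    glmm_candidates: str = "final-only",
) -> dict:
    """Simulate a study, write it to disk, and run the full analysis on it."""
    from .synthetic_data import SimConfig, simulate_dataset, write_dataset

    work = Path(work_dir)
    data = work / "data"
    sim = simulate_dataset(SimConfig(window=window), seed=seed)
    write_dataset(sim, data, overwrite=True)
    config = RunConfig(
        data_dir=data, out_dir=work / "report", window=window, seed=seed,
        glmm_candidates=glmm_candidates,
    )
    return run_analysis(config)
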