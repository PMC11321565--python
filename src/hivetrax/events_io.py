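"""Reading, validating and aggregating RFID hive-entrance registrations.

The monitoring hardware consists of a tunnel reader at each hive entrance
with two internal antennas.  A bee crossing the outer antenna and then the
inner antenna has *arrived*; the opposite order is a *departure*; a read on
one antenna only (or any read from a single-antenna reader) has *unknown*
direction.  Timestamps are logged in UTC and analysed in local civil time.

This module provides

* :func:`parse_registrations` / :func:`write_registrations` — delimited-text
  I/O with line-level error collection,
* :func:`derive_direction` — direction inference from raw antenna reads,
* :func:`localize` / :func:`diurnal_interval` — timezone handling and the
  four diurnal intervals (MORNING/MIDDAY/EVENING/NIGHT),
* :func:`build_hourly_counts` — the zero-filled per-hive hourly count table
  with weather covariates that feeds the count model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Registration",
    "RawRead",
    "BeeRecord",
    "Dialect",
    "ParseError",
    "parse_registrations",
    "write_registrations",
    "parse_roster",
    "derive_direction",
    "localize",
    "diurnal_interval",
    "localize_and_label",
    "build_hourly_counts",
    "INTERVALS",
    "STUDY_WINDOW",
]

INTERVALS = ("MORNING", "MIDDAY", "EVENING", "NIGHT")

#: Observation window of the motivating field season (used for validation).
STUDY_WINDOW = (date(2022, 5, 2), date(2022, 8, 31))

_DIRECTIONS = ("arrival", "departure", "unknown")
_ANTENNAS = ("inner", "outer", "single")


@dataclass(frozen=True)
class Registration:
    """One classified hive-entrance record for a tagged bee."""

    tag_id: str
    hive_id: str
    timestamp_utc: datetime
    antenna: str = "single"
    direction: str = "unknown"

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}: {self.direction!r}")
        if self.antenna not in _ANTENNAS:
            raise ValueError(f"antenna must be one of {_ANTENNAS}: {self.antenna!r}")


@dataclass(frozen=True)
class RawRead:
    """A single antenna read before direction inference."""

    tag_id: str
    hive_id: str
    timestamp_utc: datetime
    antenna: str  # "inner" or "outer"


@dataclass(frozen=True)
class BeeRecord:
    """Roster entry for one tagged individual."""

    tag_id: str
    individual_type: str  # "drone" | "worker"
    subspecies: str  # "Buck" | "Mel"
    natal_hive: str
    tagging_date: date
    cohort: str  # "spring" | "summer"


@dataclass
class Dialect:
    """Column layout of a delimited registration/roster file."""

    delimiter: str = ","
    columns: Sequence[str] = ("timestamp_utc", "hive_id", "antenna", "tag_id", "direction")
    timestamp_format: str | None = None  # None -> ISO-8601
    header: bool = True


@dataclass(frozen=True)
class ParseError:
    line_number: int
    line: str
    reason: str


def _parse_timestamp(text: str, fmt: str | None) -> datetime:
    if fmt is not None:
        ts = datetime.strptime(text, fmt)
    else:
        ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def parse_registrations(
    path: str | Path,
    dialect: Dialect | None = None,
) -> tuple[list[Registration], list[ParseError]]:
    """Read a registration log, collecting malformed lines instead of dropping them.

    Returns ``(registrations, errors)``; an unreadable file raises.
    """
    dialect = dialect or Dialect()
    cols = list(dialect.columns)
    regs: list[Registration] = []
    errors: list[ParseError] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for i, row in enumerate(reader, start=1):
            if dialect.header and i == 1:
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(cols):
                errors.append(ParseError(i, dialect.delimiter.join(row), "wrong field count"))
                continue
            rec = dict(zip(cols, (c.strip() for c in row)))
            try:
                ts = _parse_timestamp(rec["timestamp_utc"], dialect.timestamp_format)
                regs.append(
                    Registration(
                        tag_id=rec["tag_id"],
                        hive_id=rec["hive_id"],
                        timestamp_utc=ts,
                        antenna=rec.get("antenna", "single") or "single",
                        direction=rec.get("direction", "unknown") or "unknown",
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(ParseError(i, dialect.delimiter.join(row), str(exc)))
    return regs, errors


def write_registrations(
    regs: Iterable[Registration],
    path: str | Path,
    dialect: Dialect | None = None,
) -> None:
    """Write registrations in the same dialect :func:`parse_registrations` reads."""
    dialect = dialect or Dialect()
    cols = list(dialect.columns)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        if dialect.header:
            writer.writerow(cols)
        for r in regs:
            rec = {
                "timestamp_utc": r.timestamp_utc.strftime("%Y-%m-%dT%H:%M:%S.%f+00:00"),
                "hive_id": r.hive_id,
                "antenna": r.antenna,
                "tag_id": r.tag_id,
                "direction": r.direction,
            }
            writer.writerow([rec[c] for c in cols])


def parse_roster(path: str | Path, delimiter: str = ",") -> list[BeeRecord]:
    """Read a tagging roster (tag_id, individual_type, subspecies, natal_hive,
    tagging_date ISO, cohort)."""
    out: list[BeeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter=delimiter):
            tag = rec["tag_id"].strip()
            if tag in seen:
                raise ValueError(f"duplicate tag_id in roster: {tag}")
            seen.add(tag)
            out.append(
                BeeRecord(
                    tag_id=tag,
                    individual_type=rec["individual_type"].strip(),
                    subspecies=rec["subspecies"].strip(),
                    natal_hive=rec["natal_hive"].strip(),
                    tagging_date=date.fromisoformat(rec["tagging_date"].strip()),
                    cohort=rec["cohort"].strip(),
                )
            )
    return out


def write_roster(roster: Iterable[BeeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["tag_id", "individual_type", "subspecies", "natal_hive", "tagging_date", "cohort"]
        )
        for b in roster:
            writer.writerow(
                [b.tag_id, b.individual_type, b.subspecies, b.natal_hive,
                 b.tagging_date.isoformat(), b.cohort]
            )


# ---------------------------------------------------------------------------
# direction inference


def derive_direction(
    raw_reads: Sequence[RawRead],
    pairing_window: float = 2.0,
) -> list[Registration]:
    """Infer movement direction from raw two-antenna reads for one tag at one reader.

    Consecutive reads on opposite antennas within ``pairing_window`` seconds
    form one crossing: outer-then-inner is an arrival, inner-then-outer a
    departure, both stamped at the later read.  Any read that cannot be
    paired becomes a single ``unknown`` registration.  Every raw read
    contributes to exactly one output record.
    """
    if pairing_window <= 0:
        raise ValueError("pairing_window must be positive")
    times = [r.timestamp_utc for r in raw_reads]
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("raw reads must be sorted by time")
    out: list[Registration] = []
    i = 0
    n = len(raw_reads)
    while i < n:
        r = raw_reads[i]
        if i + 1 < n:
            nxt = raw_reads[i + 1]
            dt = (nxt.timestamp_utc - r.timestamp_utc).total_seconds()
            if r.antenna != nxt.antenna and dt <= pairing_window:
                direction = "arrival" if r.antenna == "outer" else "departure"
                out.append(
                    Registration(
                        tag_id=r.tag_id,
                        hive_id=r.hive_id,
                        timestamp_utc=nxt.timestamp_utc,
                        antenna="inner" if direction == "arrival" else "outer",
                        direction=direction,
                    )
                )
                i += 2
                continue
        out.append(
            Registration(
                tag_id=r.tag_id,
                hive_id=r.hive_id,
                timestamp_utc=r.timestamp_utc,
                antenna="single",
                direction="unknown",
            )
        )
        i += 1
    return out


# ---------------------------------------------------------------------------
# timezone and diurnal intervals


def localize(ts_utc: datetime, utc_offset_hours: float = 2.0) -> datetime:
    """Convert a UTC instant to local civil time at a fixed offset.

    The default offset (+2 h) is Swedish daylight-saving time, which covers
    the whole study window; a +1 h policy (winter CET) is available for
    general use.
    """
    if ts_utc.tzinfo is None:
        ts_utc = ts_utc.replace(tzinfo=timezone.utc)
    return ts_utc.astimezone(timezone(timedelta(hours=utc_offset_hours)))


def diurnal_interval(local_time: datetime | time) -> str:
    """Map a local wall-clock time to its diurnal interval.

    Half-open, left-closed bins: [06,11) MORNING, [11,16) MIDDAY,
    [16,21) EVENING, [21,06) NIGHT.  Every time of day maps to exactly one
    interval.
    """
    h = local_time.hour
    if 6 <= h < 11:
        return "MORNING"
    if 11 <= h < 16:
        return "MIDDAY"
    if 16 <= h < 21:
        return "EVENING"
    return "NIGHT"


def localize_and_label(
    reg: Registration, utc_offset_hours: float = 2.0
) -> tuple[datetime, str]:
    """Local instant and diurnal interval of one registration."""
    local = localize(reg.timestamp_utc, utc_offset_hours)
    return local, diurnal_interval(local)


# ---------------------------------------------------------------------------
# hourly count table


@dataclass
class CountReport:
    """Bookkeeping for the conservation invariant of :func:`build_hourly_counts`.

    ``retained + excluded_post_tag + excluded_out_of_window + off_grid
    + other_type + unresolvable == n_parsed``.
    """

    n_parsed: int = 0
    retained: int = 0
    excluded_post_tag: int = 0
    excluded_out_of_window: int = 0
    off_grid: int = 0
    other_type: int = 0
    unresolvable: int = 0
    unresolvable_tags: list[str] = field(default_factory=list)
    weather_gap_rows: int = 0

    def conserved(self) -> bool:
        return (
            self.retained
            + self.excluded_post_tag
            + self.excluded_out_of_window
            + self.off_grid
            + self.other_type
            + self.unresolvable
            == self.n_parsed
        )


def _hourly_weather(weather: pd.DataFrame, min_records: int = 6) -> pd.DataFrame:
    """Aggregate a 5-minute weather series to hourly covariates.

    Mean for temperature / wind / humidity, sum for rain; an hour with fewer
    than ``min_records`` of the 12 expected 5-minute records gets NA
    covariates.
    """
    w = weather.copy()
    ts = pd.to_datetime(w["timestamp_local"])
    w["date"] = ts.dt.date
    w["hour"] = ts.dt.hour
    grouped = w.groupby(["date", "hour"])
    agg = grouped.agg(
        temperature=("temperature", "mean"),
        wind=("wind_speed", "mean"),
        humidity=("humidity", "mean"),
        rain_sum=("rain", "sum"),
        n_records=("temperature", "size"),
    ).reset_index()
    sparse = agg["n_records"] < min_records
    agg.loc[sparse, ["temperature", "wind", "humidity", "rain_sum"]] = np.nan
    return agg.drop(columns="n_records")


def build_hourly_counts(
    regs: Sequence[Registration],
    roster: Sequence[BeeRecord],
    weather: pd.DataFrame,
    light: pd.DataFrame,
    window: tuple[date, date],
    individual_type: str = "drone",
    utc_offset_hours: float = 2.0,
    post_tag_exclusion_days: int = 2,
    hives: pd.DataFrame | None = None,
    mask_mel_spring_drones: bool = True,
) -> tuple[pd.DataFrame, CountReport]:
    """Build the zero-filled per-hive hourly count table with covariates.

    All movement directions are counted.  The grid holds exactly 24 rows per
    hive per retained date; dates within ``post_tag_exclusion_days`` calendar
    days after a cohort tagging event are excluded entirely (entrance traffic
    there reflects tag-related evictions rather than normal activity).
    Counts for Mel-subspecies hives in spring are set to NA for drones when
    ``mask_mel_spring_drones`` (no Mel drones could be tagged in spring).

    Parameters
    ----------
    weather
        5-minute series with columns ``timestamp_local, temperature,
        humidity, rain, wind_speed``.
    light
        Hourly series with columns ``timestamp_local, light`` (W/m^2 PAR).
    hives
        Optional table ``hive_id, subspecies`` defining the grid; defaults
        to the roster's natal hives of the requested individual type's
        colonies (i.e. the tagged, direction-reading hives).

    Returns
    -------
    (table, report)
        ``table`` has one row per hive x date x hour with columns
        ``hive_id, date, hour, count, age, temperature, light, wind,
        rain_sum, humidity, interval, subspecies, season``; ``report``
        carries the registration bookkeeping.
    """
    by_tag = {b.tag_id: b for b in roster}
    report = CountReport(n_parsed=len(regs))

    # cohort tagging dates (apiary-wide events)
    cohort_dates: dict[str, date] = {}
    for b in roster:
        prev = cohort_dates.get(b.cohort)
        if prev is None or b.tagging_date < prev:
            cohort_dates[b.cohort] = b.tagging_date
    if not cohort_dates:
        raise ValueError("empty roster")
    summer_start = cohort_dates.get("summer")

    excluded_dates: set[date] = set()
    for t0 in cohort_dates.values():
        for k in range(post_tag_exclusion_days + 1):
            excluded_dates.add(t0 + timedelta(days=k))

    if hives is None:
        hive_ss = sorted(
            {(b.natal_hive, b.subspecies) for b in roster if b.individual_type == individual_type}
        )
    else:
        hive_ss = sorted(zip(hives["hive_id"].astype(str), hives["subspecies"].astype(str)))
    grid_hives = [h for h, _ in hive_ss]
    subspecies_of = dict(hive_ss)

    start, end = window
    # valid grid dates with their season and cohort age, fixed before counting
    date_info: dict[date, tuple[str, int]] = {}
    for k in range((end - start).days + 1):
        d = start + timedelta(days=k)
        if d in excluded_dates:
            continue
        season = "spring" if (summer_start is None or d < summer_start) else "summer"
        tag_date = cohort_dates.get(season)
        if tag_date is None or d < tag_date:
            continue  # before the first tagging event of that season
        date_info[d] = (season, (d - tag_date).days)

    counts: dict[tuple[str, date, int], int] = {}
    for r in regs:
        bee = by_tag.get(r.tag_id)
        if bee is None:
            report.unresolvable += 1
            if r.tag_id not in report.unresolvable_tags:
                report.unresolvable_tags.append(r.tag_id)
            continue
        if bee.individual_type != individual_type:
            report.other_type += 1
            continue
        local = localize(r.timestamp_utc, utc_offset_hours)
        d = local.date()
        if d in excluded_dates:
            report.excluded_post_tag += 1
            continue
        if d not in date_info:
            report.excluded_out_of_window += 1
            continue
        if r.hive_id not in subspecies_of:
            report.off_grid += 1
            continue
        key = (r.hive_id, d, local.hour)
        counts[key] = counts.get(key, 0) + 1
        report.retained += 1

    rows = []
    for hive in grid_hives:
        ss = subspecies_of[hive]
        for d, (season, age) in date_info.items():
            for h in range(24):
                rows.append(
                    (hive, d, h, float(counts.get((hive, d, h), 0)), age, ss, season,
                     diurnal_interval(time(hour=h)))
                )
    table = pd.DataFrame(
        rows,
        columns=["hive_id", "date", "hour", "count", "age", "subspecies", "season", "interval"],
    )

    hourly_w = _hourly_weather(weather)
    lt = light.copy()
    lts = pd.to_datetime(lt["timestamp_local"])
    lt["date"] = lts.dt.date
    lt["hour"] = lts.dt.hour
    lt = lt[["date", "hour", "light"]]

    table = table.merge(hourly_w, on=["date", "hour"], how="left")
    table = table.merge(lt, on=["date", "hour"], how="left")
    report.weather_gap_rows = int(
        table[["temperature", "wind", "rain_sum", "light"]].isna().any(axis=1).sum()
    )

    if individual_type == "drone" and mask_mel_spring_drones:
        mask = (table["subspecies"] == "Mel") & (table["season"] == "spring")
        table.loc[mask, "count"] = np.nan

    cols = ["hive_id", "date", "hour", "count", "age", "temperature", "light", "wind",
            "rain_sum", "humidity", "interval", "subspecies", "season"]
    return table[cols], report
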