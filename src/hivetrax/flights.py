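"""Flight reconstruction and duration-based behaviour classification.

A departure and its subsequent arrival at any hive entrance form one flight.
Flight duration maps onto behaviour categories: under 3 min are quick
defecation/orientation exits, 3-10 min orientation flights, and 10-30,
30-60 and >60 min short, long and very long mating flights (for drones;
worker flights are binned identically for comparison only).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events_io import BeeRecord, Registration, diurnal_interval, localize

__all__ = [
    "Flight",
    "CATEGORIES",
    "categorize_flight",
    "reconstruct_flights",
    "flight_summary",
]

CATEGORIES = ("<3", "3–10", "10–30", "30–60", ">60")
_EDGES = (3.0, 10.0, 30.0, 60.0)


@dataclass(frozen=True)
class Flight:
    """One departure -> subsequent-arrival span for a tagged bee."""

    tag_id: str
    departure_time: datetime  # local
    arrival_time: datetime  # local
    departure_hive: str
    arrival_hive: str
    duration: float  # minutes
    category: str
    interval: str  # diurnal interval of the departure
    drift: bool  # arrival hive differs from the natal hive


def categorize_flight(duration: float) -> str:
    """Behaviour category for a flight duration in minutes (left-closed bins)."""
    if not duration > 0:
        raise ValueError(f"flight duration must be positive, got {duration}")
    for edge, cat in zip(_EDGES, CATEGORIES):
        if duration < edge:
            return cat
    return CATEGORIES[-1]


def reconstruct_flights(
    regs: Sequence[Registration],
    bee: BeeRecord,
    max_gap_hours: float = 24.0,
    utc_offset_hours: float = 2.0,
) -> tuple[list[Flight], list[tuple[Registration, str]]]:
    """Pair departures with their subsequent arrivals for one tag.

    Each departure is matched to the next arrival (at any hive) with no
    intervening departure; a departure superseded by a later departure is
    reported unpaired (the new departure proves an unrecorded return).
    Unknown-direction records are ignored for pairing but listed in the
    report.  Pairs spanning more than ``max_gap_hours`` are treated as
    detection failure, not flights.

    Returns ``(flights, unpaired)`` where ``unpaired`` holds
    ``(registration, reason)`` tuples.
    """
    times = [r.timestamp_utc for r in regs]
    if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("registrations must be sorted by time")
    flights: list[Flight] = []
    unpaired: list[tuple[Registration, str]] = []
    pending: Registration | None = None
    for r in regs:
        if r.direction == "unknown":
            unpaired.append((r, "unknown direction"))
            continue
        if r.direction == "departure":
            if pending is not None:
                unpaired.append((pending, "superseded by later departure"))
            pending = r
            continue
        # arrival
        if pending is None:
            unpaired.append((r, "arrival without prior departure"))
            continue
        gap_h = (r.timestamp_utc - pending.timestamp_utc).total_seconds() / 3600.0
        if gap_h > max_gap_hours:
            unpaired.append((pending, "gap exceeds max_gap"))
            unpaired.append((r, "gap exceeds max_gap"))
            pending = None
            continue
        dep_local = localize(pending.timestamp_utc, utc_offset_hours)
        arr_local = localize(r.timestamp_utc, utc_offset_hours)
        duration = (r.timestamp_utc - pending.timestamp_utc).total_seconds() / 60.0
        if duration <= 0:
            unpaired.append((pending, "non-positive duration"))
            unpaired.append((r, "non-positive duration"))
            pending = None
            continue
        flights.append(
            Flight(
                tag_id=bee.tag_id,
                departure_time=dep_local,
                arrival_time=arr_local,
                departure_hive=pending.hive_id,
                arrival_hive=r.hive_id,
                duration=duration,
                category=categorize_flight(duration),
                interval=diurnal_interval(dep_local),
                drift=r.hive_id != bee.natal_hive,
            )
        )
        pending = None
    if pending is not None:
        unpaired.append((pending, "no subsequent arrival"))
    return flights, unpaired


def flights_frame(flights: Iterable[Flight]) -> pd.DataFrame:
    """Tidy DataFrame view of a flight list."""
    return pd.DataFrame(
        [
            {
                "tag_id": f.tag_id,
                "departure_time": f.departure_time,
                "arrival_time": f.arrival_time,
                "departure_hive": f.departure_hive,
                "arrival_hive": f.arrival_hive,
                "duration_min": f.duration,
                "category": f.category,
                "interval": f.interval,
                "drift": f.drift,
            }
            for f in flights
        ]
    )


def flight_summary(
    flights: Sequence[Flight],
    group_keys: Sequence[str] = ("category",),
    roster: Mapping[str, BeeRecord] | None = None,
) -> pd.DataFrame:
    """Absolute and relative flight frequencies by the requested grouping.

    ``group_keys`` may contain ``category``, ``interval``, ``hour`` (of the
    departure) and, when a roster mapping is supplied, ``subspecies``,
    ``individual_type`` and ``cohort``.  Relative shares sum to 1 over the
    whole table (and hence within each margin when a single key is used).
    """
    if not flights:
        return pd.DataFrame(columns=[*group_keys, "n", "share"])
    df = flights_frame(flights)
    df["hour"] = [f.departure_time.hour for f in flights]
    if roster is not None:
        df["subspecies"] = [roster[f.tag_id].subspecies for f in flights]
        df["individual_type"] = [roster[f.tag_id].individual_type for f in flights]
        df["cohort"] = [roster[f.tag_id].cohort for f in flights]
    bad = set(group_keys) - set(df.columns)
    if bad:
        raise KeyError(f"unknown group keys: {sorted(bad)}")
    tab = df.groupby(list(group_keys), observed=True).size().reset_index(name="n")
    tab["share"] = tab["n"] / tab["n"].sum()
    return tab.sort_values(list(group_keys)).reset_index(drop=True)
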