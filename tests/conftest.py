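from __future__ import annotations

from datetime import date, datetime, timezone

import numpy as np
import pytest

from hivetrax.events_io import BeeRecord, RawRead, Registration


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests."""
    from hivetrax.synthetic_data import SimConfig, simulate_dataset

    cfg = SimConfig(
        window=(date(2022, 5, 2), date(2022, 6, 30)),
        n_drones_per_hive_per_cohort=10,
        n_workers_per_hive_per_cohort=6,
    )
    return simulate_dataset(cfg, seed=12345)


def utc(*args) -> datetime:
    return datetime(*args, tzinfo=timezone.utc)


def reg(tag="T1", hive="H1", ts=None, direction="unknown", antenna="single") -> Registration:
    return Registration(tag_id=tag, hive_id=hive,
                        timestamp_utc=ts or utc(2022, 6, 1, 12, 0, 0),
                        antenna=antenna, direction=direction)


def bee(tag="T1", itype="drone", subspecies="Buck", hive="H1",
        tagging=date(2022, 5, 18), cohort="spring") -> BeeRecord:
    return BeeRecord(tag_id=tag, individual_type=itype, subspecies=subspecies,
                     natal_hive=hive, tagging_date=tagging, cohort=cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20220518)
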