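import datetime as dt

import pytest

from burdensim import (
    OccurrenceDataset,
    OccurrenceRecord,
    RemainingLifeModel,
    Victim,
    default_catalogue,
)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def life44():
    return RemainingLifeModel(mode="constant", constant_years=44.4)


def make_record(i, kind="incident", cause="SIM3", victims=(), date=None):
    return OccurrenceRecord(
        id=f"OCC{i:04d}",
        date=date or dt.date(2010, 1, 1) + dt.timedelta(days=i),
        kind=kind,
        cause=cause,
        victims=tuple(victims),
    )


def make_dataset(records, span_years=4.6):
    return OccurrenceDataset(records=tuple(records), span_years=span_years)


@pytest.fixture
def small_dataset():
    """Three incidents (four victims, one fatal) and two near misses."""
    return make_dataset(
        [
            make_record(0, victims=[Victim(30, ("Sprained or twisted",))]),
            make_record(
                1,
                cause="SIM2",
                victims=[
                    Victim(55, ("Poisoning", "Sprained or twisted")),
                    Victim(12, ("External bruise",)),
                ],
            ),
            make_record(2, cause="RCNE", victims=[Victim(70, ("Fatal injury",), fatal=True)]),
            make_record(3, kind="near_miss", cause="SIM3"),
            make_record(4, kind="near_miss", cause="SIM1"),
        ]
    )
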