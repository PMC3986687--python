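"""Historical occurrence records: data model, CSV I/O, empirical fits.

An *occurrence* is either an incident (an event with a consequence such as
an injury) or a near miss (elevated exposure without consequence).  Each
occurrence carries a causal category: SIM1 (inadequate regulatory
controls), SIM2 (noncompliance with controls), SIM3 (factors outside the
regulatory purview, e.g. user behaviour) or RCNE (root cause not
established).

Records are exchanged in a long-format CSV, one row per victim, with the
occurrence-level columns repeated; occurrences without victims appear as a
single row with the victim columns empty.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalogue import InjuryCatalogue, RemainingLifeModel, daly_for_injury

__all__ = [
    "CAUSES",
    "KINDS",
    "Victim",
    "OccurrenceRecord",
    "OccurrenceDataset",
    "EmpiricalDistributions",
    "RecordsError",
    "FitError",
    "read_records",
    "write_records",
    "fit_injury_distribution",
    "fit_cause_distribution",
    "fit_injuries_per_victim",
    "fit_distributions",
    "observed_dalys",
]

CAUSES = ("SIM1", "SIM2", "SIM3", "RCNE")
KINDS = ("incident", "near_miss")

RECORDS_COLUMNS = (
    "occurrence_id",
    "date",
    "kind",
    "cause",
    "victim_index",
    "age",
    "fatal",
    "injuries",
)


class RecordsError(ValueError):
    """Raised on malformed records files."""


class FitError(ValueError):
    """Raised when an empirical distribution cannot be fitted."""


@dataclass(frozen=True)
class Victim:
    age: float
    injuries: tuple[str, ...]
    fatal: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"victim age must be >= 0, got {self.age}")

    def effective_injuries(self, catalogue: InjuryCatalogue) -> tuple[str, ...]:
        """Injuries scored for this victim.

        A death overrides every other sustained injury: a fatal victim
        contributes the single fatal type regardless of what else was
        recorded.
        """
        if self.fatal or catalogue.fatal.name in self.injuries:
            return (catalogue.fatal.name,)
        return self.injuries

    def daly(self, catalogue: InjuryCatalogue, life: RemainingLifeModel) -> float:
        """Total DALYs for this victim (remaining life if fatal)."""
        rl = life.remaining_life(self.age)
        return sum(
            daly_for_injury(catalogue[name], rl)
            for name in self.effective_injuries(catalogue)
        )


@dataclass(frozen=True)
class OccurrenceRecord:
    id: str
    date: dt.date
    kind: str
    cause: str
    victims: tuple[Victim, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown occurrence kind {self.kind!r}")
        if self.cause not in CAUSES:
            raise ValueError(f"unknown causal category {self.cause!r}")
        if self.kind == "near_miss" and any(
            v.injuries or v.fatal for v in self.victims
        ):
            raise ValueError(
                f"near-miss occurrence {self.id!r} cannot have injured victims"
            )


@dataclass(frozen=True)
class OccurrenceDataset:
    """A set of occurrence records observed over ``span_years``."""

    records: tuple[OccurrenceRecord, ...]
    span_years: float

    def __post_init__(self) -> None:
        if self.span_years <= 0:
            raise ValueError("observation span must be > 0 years")

    @property
    def n_incidents(self) -> int:
        return sum(r.kind == "incident" for r in self.records)

    @property
    def n_near_misses(self) -> int:
        return sum(r.kind == "near_miss" for r in self.records)

    def victims(self) -> list[Victim]:
        return [v for r in self.records for v in r.victims]


@dataclass(frozen=True)
class EmpiricalDistributions:
    """Empirical sampling distributions fitted from an occurrence history.

    ``injury_dist`` and ``cause_dist`` are categorical probabilities (each
    summing to 1); ``ages`` is the raw sample of victim ages to resample
    from; ``injuries_per_victim`` is categorical over 1..K.
    """

    injury_dist: Mapping[str, float]
    cause_dist: Mapping[str, float]
    ages: tuple[float, ...]
    injuries_per_victim: Mapping[int, float]

    def __post_init__(self) -> None:
        for label, dist in (
            ("injury_dist", self.injury_dist),
            ("cause_dist", self.cause_dist),
            ("injuries_per_victim", self.injuries_per_victim),
        ):
            probs = np.array(list(dist.values()), dtype=float)
            if probs.size == 0:
                raise ValueError(f"{label} is empty")
            if (probs < 0).any():
                raise ValueError(f"{label} has negative mass")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError(f"{label} sums to {probs.sum()}, not 1")


def _parse_date(text: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise RecordsError(f"line {line}: unparseable date {text!r}") from exc


def read_records(
    path: str | Path, catalogue: InjuryCatalogue, span_years: float | None = None
) -> OccurrenceDataset:
    """Read a long-format records CSV into an :class:`OccurrenceDataset`.

    Rows sharing an ``occurrence_id`` are merged into one record.  Injury
    names are validated against ``catalogue``; kind/cause against their
    closed vocabularies.  ``span_years`` defaults to the calendar span of
    the record dates (minimum one day).
    """
    # occurrence_id -> (date, kind, cause, [victims])
    merged: dict[str, tuple[dt.date, str, str, list[Victim]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(RECORDS_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise RecordsError(
                f"records file must have columns {list(RECORDS_COLUMNS)}"
            )
        for line, row in enumerate(reader, start=2):
            oid = row["occurrence_id"]
            date = _parse_date(row["date"], line)
            kind, cause = row["kind"], row["cause"]
            if kind not in KINDS:
                raise RecordsError(f"line {line}: unknown kind {kind!r}")
            if cause not in CAUSES:
                raise RecordsError(f"line {line}: unknown cause {cause!r}")
            if oid not in merged:
                merged[oid] = (date, kind, cause, [])
            if row["victim_index"].strip() == "":
                continue  # victimless occurrence row
            injuries = tuple(
                name.strip()
                for name in row["injuries"].split(";")
                if name.strip()
            )
            for name in injuries:
                if name not in catalogue:
                    raise RecordsError(
                        f"line {line}: unknown injury type {name!r}"
                    )
            try:
                victim = Victim(
                    age=float(row["age"]),
                    injuries=injuries,
                    fatal=row["fatal"].strip() in ("1", "true", "True"),
                )
            except ValueError as exc:
                raise RecordsError(f"line {line}: {exc}") from exc
            merged[oid][3].append(victim)

    records = []
    for oid, (date, kind, cause, victims) in merged.items():
        try:
            records.append(
                OccurrenceRecord(
                    id=oid, date=date, kind=kind, cause=cause, victims=tuple(victims)
                )
            )
        except ValueError as exc:
            raise RecordsError(str(exc)) from exc
    if span_years is None:
        if not records:
            raise RecordsError("empty records file and no span_years given")
        dates = [r.date for r in records]
        span_years = max((max(dates) - min(dates)).days / 365.25, 1 / 365.25)
    return OccurrenceDataset(records=tuple(records), span_years=span_years)


def write_records(dataset: OccurrenceDataset, path: str | Path) -> None:
    """Write a dataset in the identical long-format CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORDS_COLUMNS)
        for rec in dataset.records:
            base = [rec.id, rec.date.isoformat(), rec.kind, rec.cause]
            if not rec.victims:
                writer.writerow(base + ["", "", "", ""])
                continue
            for i, v in enumerate(rec.victims):
                writer.writerow(
                    base
                    + [i, repr(v.age), "1" if v.fatal else "0", ";".join(v.injuries)]
                )


def fit_injury_distribution(
    dataset: OccurrenceDataset,
    catalogue: InjuryCatalogue,
    pool_mass: float = 0.01,
) -> dict[str, float]:
    """Relative-frequency injury-type distribution with unobserved pooling.

    Observed types receive their relative frequency scaled by
    ``1 - pool_mass`` whenever at least one catalogue type went unobserved;
    the reserved ``pool_mass`` is split equally among the unobserved types
    so they remain reachable during simulation, with a lesser chance.  A
    recorded death counts as one fatal-injury observation and overrides
    the victim's other injuries.
    """
    if not 0 <= pool_mass < 1:
        raise ValueError("pool_mass must be in [0, 1)")
    counts: dict[str, int] = {name: 0 for name in catalogue.names}
    for victim in dataset.victims():
        for name in victim.effective_injuries(catalogue):
            counts[name] += 1
    total = sum(counts.values())
    if total == 0:
        raise FitError("dataset contains no sustained injuries")
    unobserved = [name for name, c in counts.items() if c == 0]
    if not unobserved:
        return {name: c / total for name, c in counts.items()}
    scale = (1.0 - pool_mass) / total
    dist = {name: c * scale for name, c in counts.items()}
    for name in unobserved:
        dist[name] = pool_mass / len(unobserved)
    return dist


def fit_cause_distribution(dataset: OccurrenceDataset) -> dict[str, float]:
    """Relative frequencies of the four causal categories over all records."""
    if not dataset.records:
        raise FitError("cannot fit cause distribution from an empty dataset")
    counts = {cause: 0 for cause in CAUSES}
    for rec in dataset.records:
        counts[rec.cause] += 1
    n = len(dataset.records)
    return {cause: c / n for cause, c in counts.items()}


def fit_injuries_per_victim(
    dataset: OccurrenceDataset, catalogue: InjuryCatalogue, max_injuries: int = 4
) -> dict[int, float]:
    """Categorical over 1..K of injuries sustained per victim, capped at K."""
    if max_injuries < 1:
        raise ValueError("max_injuries must be >= 1")
    counts = {k: 0 for k in range(1, max_injuries + 1)}
    total = 0
    for victim in dataset.victims():
        n = len(victim.effective_injuries(catalogue))
        if n == 0:
            continue
        counts[min(n, max_injuries)] += 1
        total += 1
    if total == 0:
        raise FitError("dataset contains no victims with injuries")
    return {k: c / total for k, c in counts.items()}


def fit_distributions(
    dataset: OccurrenceDataset,
    catalogue: InjuryCatalogue,
    pool_mass: float = 0.01,
    max_injuries: int = 4,
) -> EmpiricalDistributions:
    """Fit all four empirical distributions needed by the simulator."""
    ages = tuple(v.age for v in dataset.victims())
    return EmpiricalDistributions(
        injury_dist=fit_injury_distribution(dataset, catalogue, pool_mass),
        cause_dist=fit_cause_distribution(dataset),
        ages=ages,
        injuries_per_victim=fit_injuries_per_victim(dataset, catalogue, max_injuries),
    )


def observed_dalys(
    dataset: OccurrenceDataset,
    catalogue: InjuryCatalogue,
    life: RemainingLifeModel,
    period: str = "quarter",
) -> pd.Series:
    """Historically observed DALY totals per calendar period.

    Returns a Series indexed by pandas ``Period`` (quarterly or yearly)
    covering the full range of record dates; periods without injuries
    total 0.  Fatal victims contribute their remaining life expectancy,
    non-fatal victims the sum of their injury DALYs; victimless
    occurrences (and near misses) contribute 0.
    """
    freq = {"quarter": "Q", "year": "Y"}.get(period)
    if freq is None:
        raise ValueError(f"period must be 'quarter' or 'year', got {period!r}")
    if not dataset.records:
        return pd.Series(dtype=float)
    rows = [
        (pd.Period(rec.date, freq=freq), sum(v.daly(catalogue, life) for v in rec.victims))
        for rec in dataset.records
    ]
    df = pd.DataFrame(rows, columns=["period", "daly"])
    totals = df.groupby("period").daly.sum().sort_index()
    full = pd.period_range(totals.index.min(), totals.index.max(), freq=freq)
    return totals.reindex(full, fill_value=0.0).rename("daly")
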