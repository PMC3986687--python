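"""Injury-type disability catalogue and single-injury DALY computation.

The burden of a sustained injury is expressed in disability-adjusted life
years (DALYs) combining a short-term (acute) component and a long-term
(chronic) component::

    DALY = st_weight * st_duration
         + lt_weight * fraction_long_term * remaining_life

where ``remaining_life`` is the victim's remaining life expectancy (years)
at the time of the occurrence.  Disability weights lie in [0, 1]; 0 means
full health and 1 is equivalent to death.  A fatality is encoded as a
special injury type with ``st_weight = st_duration = 0`` and
``lt_weight = fraction_long_term = 1`` so that its DALY equals the remaining
life expectancy of the deceased exactly.

The packaged default catalogue adapts AIHW/GBD disability weights to the
injury vocabulary used by a technical-safety regulator for elevating
devices (concussion, sprains, electric shock, ... plus the fatal and
"No Injury" sentinel types).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "InjuryTypeSpec",
    "InjuryCatalogue",
    "RemainingLifeModel",
    "CatalogueSchemaError",
    "load_catalogue",
    "write_catalogue",
    "default_catalogue",
    "daly_for_injury",
    "MEDIAN_REMAINING_LIFE_YEARS",
]

#: Median remaining life expectancy (years, gender-averaged) used as the
#: default long-term duration and as the one-fatality benchmark.
MEDIAN_REMAINING_LIFE_YEARS = 44.4

CATALOGUE_COLUMNS = (
    "name",
    "st_weight",
    "st_duration_years",
    "fraction_long_term",
    "lt_weight",
    "is_fatal",
)


class CatalogueSchemaError(ValueError):
    """Raised when a catalogue file violates the documented schema."""


@dataclass(frozen=True)
class InjuryTypeSpec:
    """Disability parameters for one injury type.

    Parameters
    ----------
    name
        Unique label, e.g. ``"Concussion"``.
    st_weight
        Short-term disability weight in [0, 1].
    st_duration
        Short-term duration in years (>= 0).
    frac_long_term
        Fraction of remaining life affected by the long-term disability,
        in [0, 1].
    lt_weight
        Long-term disability weight in [0, 1].
    is_fatal
        Marks the fatal sentinel type.
    comment
        Free-text provenance note (source burden-of-disease category);
        never used in computation.
    """

    name: str
    st_weight: float
    st_duration: float
    frac_long_term: float
    lt_weight: float
    is_fatal: bool = False
    comment: str = ""

    def __post_init__(self) -> None:
        for attr in ("st_weight", "frac_long_term", "lt_weight"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise CatalogueSchemaError(
                    f"{self.name!r}: {attr} = {v} outside [0, 1]"
                )
        if self.st_duration < 0:
            raise CatalogueSchemaError(
                f"{self.name!r}: st_duration = {self.st_duration} negative"
            )
        if self.is_fatal and (
            self.st_weight != 0
            or self.st_duration != 0
            or self.frac_long_term != 1
            or self.lt_weight != 1
        ):
            raise CatalogueSchemaError(
                f"{self.name!r}: fatal type must have parameters (0, 0, 1, 1)"
            )


class InjuryCatalogue:
    """Collection of :class:`InjuryTypeSpec` keyed by name.

    Contains exactly one fatal type and exactly one no-injury type (all
    four numeric parameters zero).
    """

    def __init__(self, specs: Iterable[InjuryTypeSpec]):
        self._specs: dict[str, InjuryTypeSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise CatalogueSchemaError(f"duplicate injury type {spec.name!r}")
            self._specs[spec.name] = spec
        fatal = [s for s in self._specs.values() if s.is_fatal]
        if len(fatal) != 1:
            raise CatalogueSchemaError(
                f"catalogue must contain exactly one fatal type, found {len(fatal)}"
            )
        no_injury = [
            s
            for s in self._specs.values()
            if not s.is_fatal
            and s.st_weight == s.st_duration == s.frac_long_term == s.lt_weight == 0
        ]
        if len(no_injury) != 1:
            raise CatalogueSchemaError(
                "catalogue must contain exactly one no-injury type "
                f"(all parameters zero), found {len(no_injury)}"
            )
        self._fatal = fatal[0]
        self._no_injury = no_injury[0]

    @property
    def fatal(self) -> InjuryTypeSpec:
        return self._fatal

    @property
    def no_injury(self) -> InjuryTypeSpec:
        return self._no_injury

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    def __getitem__(self, name: str) -> InjuryTypeSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InjuryCatalogue):
            return NotImplemented
        return self._specs == other._specs


@dataclass(frozen=True)
class RemainingLifeModel:
    """Remaining life expectancy (years) as a function of age.

    ``constant`` mode returns a fixed value for every age; ``table`` mode
    linearly interpolates a gender-averaged (age, remaining_years) table,
    clamping outside the tabulated age range.
    """

    mode: str = "constant"
    constant_years: float = MEDIAN_REMAINING_LIFE_YEARS
    table: Sequence[tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant":
            if self.constant_years < 0:
                raise ValueError("constant_years must be >= 0")
        else:
            ages = [a for a, _ in self.table]
            years = [y for _, y in self.table]
            if len(ages) == 0:
                raise ValueError("table mode requires a non-empty table")
            if any(y < 0 for y in years):
                raise ValueError("remaining_years must be >= 0 everywhere")
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError("table ages must be strictly increasing")

    def remaining_life(self, age: float) -> float:
        """Remaining life expectancy at ``age`` (years).  ``age`` >= 0."""
        return float(self.remaining_life_array(np.asarray([age], dtype=float))[0])

    def remaining_life_array(self, ages: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`remaining_life` over an array of ages."""
        ages = np.asarray(ages, dtype=float)
        if ages.size and ages.min() < 0:
            raise ValueError("age must be >= 0")
        if self.mode == "constant":
            return np.full(ages.shape, self.constant_years)
        xs = np.array([a for a, _ in self.table], dtype=float)
        ys = np.array([y for _, y in self.table], dtype=float)
        # np.interp clamps at both ends, the documented boundary behaviour
        return np.interp(ages, xs, ys)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RemainingLifeModel":
        """Load a life table CSV with columns ``age, remaining_years``."""
        rows: list[tuple[float, float]] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"age", "remaining_years"} <= set(
                reader.fieldnames
            ):
                raise CatalogueSchemaError(
                    "life table must have columns 'age' and 'remaining_years'"
                )
            for row in reader:
                rows.append((float(row["age"]), float(row["remaining_years"])))
        return cls(mode="table", table=tuple(rows))


def daly_for_injury(spec: InjuryTypeSpec, remaining_life: float) -> float:
    """DALY (years) attributed to one sustained injury.

    Evaluates ``st_weight * st_duration + lt_weight * frac_long_term *
    remaining_life``.  For the fatal type this equals ``remaining_life``
    exactly; for the no-injury type it is 0.
    """
    if remaining_life < 0:
        raise ValueError(f"remaining_life must be >= 0, got {remaining_life}")
    return (
        spec.st_weight * spec.st_duration
        + spec.lt_weight * spec.frac_long_term * remaining_life
    )


def _parse_catalogue_rows(reader: csv.DictReader, source: str) -> InjuryCatalogue:
    if reader.fieldnames is None:
        raise CatalogueSchemaError(f"{source}: empty catalogue file")
    missing = set(CATALOGUE_COLUMNS) - set(reader.fieldnames)
    if missing:
        raise CatalogueSchemaError(
            f"{source}: missing column(s) {sorted(missing)}"
        )
    specs = []
    for i, row in enumerate(reader, start=2):
        try:
            specs.append(
                InjuryTypeSpec(
                    name=row["name"],
                    st_weight=float(row["st_weight"]),
                    st_duration=float(row["st_duration_years"]),
                    frac_long_term=float(row["fraction_long_term"]),
                    lt_weight=float(row["lt_weight"]),
                    is_fatal=row["is_fatal"].strip() in ("1", "true", "True"),
                    comment=(row.get("comment") or ""),
                )
            )
        except (CatalogueSchemaError, ValueError) as exc:
            raise CatalogueSchemaError(f"{source}, line {i}: {exc}") from exc
    return InjuryCatalogue(specs)


def load_catalogue(path: str | Path) -> InjuryCatalogue:
    """Read an injury catalogue from a CSV file.

    Schema: ``name, st_weight, st_duration_years, fraction_long_term,
    lt_weight, is_fatal[, comment]``.  Raises
    :class:`CatalogueSchemaError` naming the offending row on any
    violation (missing column, out-of-range weight, duplicate name,
    absent fatal or no-injury row).
    """
    with open(path, newline="") as fh:
        return _parse_catalogue_rows(csv.DictReader(fh), str(path))


def write_catalogue(catalogue: InjuryCatalogue, path: str | Path) -> None:
    """Write a catalogue in the same CSV dialect ``load_catalogue`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOGUE_COLUMNS + ("comment",))
        for spec in catalogue:
            writer.writerow(
                [
                    spec.name,
                    repr(spec.st_weight),
                    repr(spec.st_duration),
                    repr(spec.frac_long_term),
                    repr(spec.lt_weight),
                    "1" if spec.is_fatal else "0",
                    spec.comment,
                ]
            )


def default_catalogue() -> InjuryCatalogue:
    """The packaged default disability-weight catalogue (15 injury types)."""
    text = resources.files("burdensim.data").joinpath("injury_catalogue.csv").read_text()
    return _parse_catalogue_rows(csv.DictReader(io.StringIO(text)), "packaged default")
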