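"""Summaries of simulated burden: percentiles, cause breakdown, per-million.

Predicted burden is reported as an empirical distribution over the
per-iteration DALY totals — a range of percentiles alongside the mean —
broken down by causal category and normalised to DALYs per million
exposed persons per year.  A one-fatality benchmark (the DALY cost of a
single death at median remaining life expectancy) accompanies every
summary as a guiding reference for decision-makers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalogue import InjuryCatalogue, RemainingLifeModel, daly_for_injury
from .records import CAUSES
from .simulate import SimulationResult

__all__ = ["BurdenSummary", "summarize", "fatality_benchmark", "histogram"]

DEFAULT_PROBS = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class BurdenSummary:
    """Summary statistics of one simulation run.

    ``mean_total`` is DALYs per horizon; ``per_million_per_year`` divides
    it by the horizon and the exposed population in millions.
    """

    mean_total: float
    percentiles: dict[float, float]
    mean_by_cause: dict[str, float]
    per_million_per_year: float
    per_million_per_year_by_cause: dict[str, float]
    fatality_benchmark: float
    n_iterations: int
    horizon_years: float
    population: float

    def to_dict(self) -> dict:
        return {
            "mean_total_dalys": self.mean_total,
            "percentiles": {str(p): v for p, v in self.percentiles.items()},
            "mean_by_cause": dict(self.mean_by_cause),
            "dalys_per_million_per_year": self.per_million_per_year,
            "dalys_per_million_per_year_by_cause": dict(
                self.per_million_per_year_by_cause
            ),
            "fatality_benchmark_dalys": self.fatality_benchmark,
            "n_iterations": self.n_iterations,
            "horizon_years": self.horizon_years,
            "population": self.population,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def fatality_benchmark(life: RemainingLifeModel, catalogue: InjuryCatalogue,
                       age: float | None = None) -> float:
    """DALYs attributed to a single fatality.

    With a constant-mode life model this is the median remaining life
    expectancy itself (the fatal type's DALY equals remaining life
    exactly); with a life table an ``age`` may be supplied, defaulting to
    the youngest tabulated age.
    """
    if life.mode == "constant":
        rl = life.constant_years
    else:
        rl = life.remaining_life(age if age is not None else life.table[0][0])
    return daly_for_injury(catalogue.fatal, rl)


def summarize(
    result: SimulationResult,
    catalogue: InjuryCatalogue,
    life: RemainingLifeModel,
    probs: Sequence[float] = DEFAULT_PROBS,
) -> BurdenSummary:
    """Summarise per-iteration DALY totals into a :class:`BurdenSummary`.

    Percentiles are empirical order statistics with linear interpolation.
    """
    if not result.iterations:
        raise ValueError("cannot summarise an empty simulation result")
    probs = tuple(probs)
    if any(not 0 < p < 1 for p in probs):
        raise ValueError("percentile probabilities must lie in (0, 1)")
    totals = result.totals()
    # sort before averaging so the summary is exactly invariant to
    # iteration order despite floating-point non-associativity
    mean_total = float(np.sort(totals).mean())
    pct_values = np.quantile(totals, probs, method="linear")
    horizon = result.config.horizon_years
    population = result.config.population
    millions = population / 1e6
    mean_by_cause = {
        c: float(np.sort(result.totals_by_cause(c)).mean()) for c in CAUSES
    }
    return BurdenSummary(
        mean_total=mean_total,
        percentiles={p: float(v) for p, v in zip(probs, pct_values)},
        mean_by_cause=mean_by_cause,
        per_million_per_year=mean_total / horizon / millions,
        per_million_per_year_by_cause={
            c: v / horizon / millions for c, v in mean_by_cause.items()
        },
        fatality_benchmark=fatality_benchmark(life, catalogue),
        n_iterations=len(result.iterations),
        horizon_years=horizon,
        population=population,
    )


def histogram(result: SimulationResult, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin edges) of per-iteration DALY totals."""
    counts, edges = np.histogram(result.totals(), bins=bins)
    return counts, edges
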