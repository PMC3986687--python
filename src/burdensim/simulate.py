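"""First- and second-order Monte Carlo simulation of future injury burden.

The first-order (inner) loop captures *variability*: for each simulated
year-ahead scenario it draws the number of occurrences from a Poisson
process at fixed rate ``lam``, then for every occurrence a causal
category, a number of injured victims (discrete uniform on 0..M), and for
every victim an age, an injury count (1..K) and that many injury types
sampled with replacement.  Each injury is scored in DALYs; a fatal draw
overrides all other injuries of that victim and scores the victim's full
remaining life expectancy.

The second-order (outer) loop captures *uncertainty* in the occurrence
rate itself: each outer draw samples a reporting-bias multiplier from a
configured distribution, recomputes ``lam``, and runs the full inner loop.
A point-mass bias distribution reduces exactly to the first-order model.

Reproducibility: a single root seed is configured; every iteration gets
its own deterministic child RNG stream keyed by (seed, outer index, inner
index), so results are bit-identical on rerun and independent of
execution order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .catalogue import InjuryCatalogue, RemainingLifeModel
from .rates import RateEstimate
from .records import CAUSES, EmpiricalDistributions, Victim

__all__ = [
    "BiasDistribution",
    "SimulationConfig",
    "IterationResult",
    "SimulationResult",
    "sample_occurrence_count",
    "sample_victim_count",
    "sample_victim",
    "run_first_order",
    "run_second_order",
    "write_results",
    "config_from_file",
]


@dataclass(frozen=True)
class BiasDistribution:
    """Distribution of the reporting-bias multiplier for the outer loop.

    ``point`` concentrates all mass at ``lo``; ``uniform`` draws from
    [lo, hi]; ``triangular`` from (lo, mode, hi).  All support must lie at
    or above 1 (a bias below 1 would mean negative unreported counts).
    """

    kind: str = "point"
    lo: float = 1.0
    hi: float | None = None
    mode: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "uniform", "triangular"):
            raise ValueError(f"unknown bias distribution kind {self.kind!r}")
        if self.lo < 1:
            raise ValueError("bias support must lie at or above 1")
        if self.kind in ("uniform", "triangular"):
            if self.hi is None or self.hi < self.lo:
                raise ValueError("bias distribution requires hi >= lo")
        if self.kind == "triangular":
            m = self.mode if self.mode is not None else (self.lo + self.hi) / 2
            if not self.lo <= m <= self.hi:
                raise ValueError("triangular mode must lie within [lo, hi]")

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.lo
        if self.kind == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        m = self.mode if self.mode is not None else (self.lo + self.hi) / 2
        return float(rng.triangular(self.lo, m, self.hi))

    def mean(self) -> float:
        if self.kind == "point":
            return self.lo
        if self.kind == "uniform":
            return (self.lo + self.hi) / 2
        m = self.mode if self.mode is not None else (self.lo + self.hi) / 2
        return (self.lo + m + self.hi) / 3


@dataclass(frozen=True)
class SimulationConfig:
    """All simulation knobs.

    Parameters
    ----------
    iterations
        Inner Monte Carlo iterations per outer draw.
    horizon_years
        Length of the simulated future window (years).
    population
        Exposed population size (persons), used for per-million reporting.
    max_victims
        M: inclusive upper bound of the discrete-uniform victim count per
        occurrence.
    max_injuries_per_victim
        K: cap on injuries sampled per victim.
    pool_mass
        Probability mass reserved for injury types never observed
        historically (see the fitting module).
    seed
        Root RNG seed; fixed seed implies bit-identical reruns.
    bias_distribution
        Reporting-bias multiplier distribution for the second-order loop.
    outer_iterations
        Outer (uncertainty) draws; only used by :func:`run_second_order`.
    age_range
        Fallback (lo, hi) for victim ages when no empirical age sample is
        available.
    """

    iterations: int = 10_000
    horizon_years: float = 1.0
    population: float = 13.4e6
    max_victims: int = 6
    max_injuries_per_victim: int = 4
    pool_mass: float = 0.01
    seed: int = 0
    bias_distribution: BiasDistribution = field(default_factory=BiasDistribution)
    outer_iterations: int = 1
    age_range: tuple[float, float] = (0.0, 90.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if self.max_victims < 0:
            raise ValueError("max_victims must be >= 0")
        if self.max_injuries_per_victim < 1:
            raise ValueError("max_injuries_per_victim must be >= 1")
        if self.outer_iterations < 1:
            raise ValueError("outer_iterations must be >= 1")


@dataclass(frozen=True)
class IterationResult:
    """One simulated scenario over the horizon."""

    n_occurrences: int
    n_victims: int
    n_fatalities: int
    dalys_by_cause: dict[str, float]
    total_dalys: float
    outer_index: int = 0
    bias: float = 1.0


@dataclass(frozen=True)
class SimulationResult:
    """All iterations plus echoes of the inputs that produced them."""

    iterations: tuple[IterationResult, ...]
    config: SimulationConfig
    distributions: EmpiricalDistributions
    rate: RateEstimate

    def totals(self) -> np.ndarray:
        return np.array([it.total_dalys for it in self.iterations])

    def totals_by_cause(self, cause: str) -> np.ndarray:
        return np.array([it.dalys_by_cause[cause] for it in self.iterations])


def config_from_file(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file.

    Keys mirror the dataclass fields; ``bias_distribution`` is a nested
    mapping (``kind``, ``lo``, ``hi``, ``mode``).
    """
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    if "bias_distribution" in payload:
        payload["bias_distribution"] = BiasDistribution(
            **payload["bias_distribution"]
        )
    if "age_range" in payload:
        payload["age_range"] = tuple(payload["age_range"])
    return SimulationConfig(**payload)


def sample_occurrence_count(
    lam: float, horizon_years: float, rng: np.random.Generator
) -> int:
    """Poisson draw of the occurrence count with mean ``lam * horizon``."""
    if lam < 0:
        raise ValueError(f"occurrence rate must be >= 0, got {lam}")
    return int(rng.poisson(lam * horizon_years))


def sample_victim_count(max_victims: int, rng: np.random.Generator) -> int:
    """Discrete-uniform victim count on {0, ..., M} inclusive."""
    if max_victims < 0:
        raise ValueError(f"max_victims must be >= 0, got {max_victims}")
    return int(rng.integers(0, max_victims + 1))


class _SamplingTables:
    """Catalogue and distribution data flattened to numpy arrays."""

    def __init__(
        self,
        dists: EmpiricalDistributions,
        catalogue: InjuryCatalogue,
        life: RemainingLifeModel,
        config: SimulationConfig,
    ):
        self.injury_names = list(dists.injury_dist)
        self.p_injury = np.array(
            [dists.injury_dist[n] for n in self.injury_names], dtype=float
        )
        self.p_injury = self.p_injury / self.p_injury.sum()
        specs = [catalogue[n] for n in self.injury_names]
        # per-type DALY pieces: acute term and chronic slope in remaining life
        self.acute = np.array([s.st_weight * s.st_duration for s in specs])
        self.chronic = np.array([s.lt_weight * s.frac_long_term for s in specs])
        self.fatal_mask = np.array([s.is_fatal for s in specs], dtype=bool)
        self.p_cause = np.array(
            [dists.cause_dist.get(c, 0.0) for c in CAUSES], dtype=float
        )
        self.p_cause = self.p_cause / self.p_cause.sum()
        self.ages = np.array(dists.ages, dtype=float)
        self.age_range = config.age_range
        K = config.max_injuries_per_victim
        counts = sorted(dists.injuries_per_victim)
        self.injury_count_values = np.minimum(np.array(counts), K)
        self.p_injury_count = np.array(
            [dists.injuries_per_victim[k] for k in counts], dtype=float
        )
        self.p_injury_count = self.p_injury_count / self.p_injury_count.sum()
        self.life = life

    def sample_ages(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.ages.size:
            return rng.choice(self.ages, size=n, replace=True)
        lo, hi = self.age_range
        return rng.uniform(lo, hi, size=n)


def sample_victim(
    dists: EmpiricalDistributions,
    catalogue: InjuryCatalogue,
    life: RemainingLifeModel,
    max_injuries_per_victim: int,
    rng: np.random.Generator,
) -> tuple[Victim, float]:
    """Draw one victim and their DALY total.

    Samples an age, an injury count (capped at K), then that many injury
    types with replacement.  Duplicated draws are each scored.  If any
    draw is the fatal type all others are discarded and the DALY is the
    victim's remaining life expectancy.
    """
    config = SimulationConfig(max_injuries_per_victim=max_injuries_per_victim)
    tables = _SamplingTables(dists, catalogue, life, config)
    age = float(tables.sample_ages(1, rng)[0])
    k = int(rng.choice(tables.injury_count_values, p=tables.p_injury_count))
    idx = rng.choice(len(tables.injury_names), size=k, p=tables.p_injury)
    rl = life.remaining_life(age)
    if tables.fatal_mask[idx].any():
        victim = Victim(age=age, injuries=(catalogue.fatal.name,), fatal=True)
        return victim, rl
    names = tuple(tables.injury_names[i] for i in idx)
    daly = float(np.sum(tables.acute[idx] + tables.chronic[idx] * rl))
    return Victim(age=age, injuries=names, fatal=False), daly


def _run_iteration(
    lam: float,
    tables: _SamplingTables,
    config: SimulationConfig,
    rng: np.random.Generator,
    outer_index: int,
    bias: float,
) -> IterationResult:
    n_occ = sample_occurrence_count(lam, config.horizon_years, rng)
    buckets = np.zeros(len(CAUSES))
    if n_occ == 0:
        by_cause = dict(zip(CAUSES, buckets))
        return IterationResult(0, 0, 0, by_cause, 0.0, outer_index, bias)

    cause_idx = rng.choice(len(CAUSES), size=n_occ, p=tables.p_cause)
    vcounts = rng.integers(0, config.max_victims + 1, size=n_occ)
    n_victims = int(vcounts.sum())
    if n_victims == 0:
        by_cause = dict(zip(CAUSES, buckets))
        return IterationResult(n_occ, 0, 0, by_cause, 0.0, outer_index, bias)

    ages = tables.sample_ages(n_victims, rng)
    rem_life = tables.life.remaining_life_array(ages)
    icounts = rng.choice(
        tables.injury_count_values, size=n_victims, p=tables.p_injury_count
    )
    n_inj = int(icounts.sum())
    type_idx = rng.choice(len(tables.injury_names), size=n_inj, p=tables.p_injury)

    # score each sampled injury, then fold back to victims by segment
    offsets = np.concatenate(([0], np.cumsum(icounts)[:-1]))
    inj_rl = np.repeat(rem_life, icounts)
    inj_daly = tables.acute[type_idx] + tables.chronic[type_idx] * inj_rl
    victim_daly = np.add.reduceat(inj_daly, offsets)
    fatal_per_victim = np.add.reduceat(
        tables.fatal_mask[type_idx].astype(float), offsets
    ) > 0
    # a death discards every other sampled injury for that victim
    victim_daly = np.where(fatal_per_victim, rem_life, victim_daly)
    n_fatalities = int(fatal_per_victim.sum())

    victim_cause = np.repeat(cause_idx, vcounts)
    buckets = np.bincount(victim_cause, weights=victim_daly, minlength=len(CAUSES))
    by_cause = dict(zip(CAUSES, buckets))
    total = float(sum(by_cause.values()))
    return IterationResult(
        n_occ, n_victims, n_fatalities, by_cause, total, outer_index, bias
    )


def _child_rng(seed: int, outer: int, inner: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, outer, inner)))


def run_first_order(
    rate: RateEstimate,
    dists: EmpiricalDistributions,
    catalogue: InjuryCatalogue,
    life: RemainingLifeModel,
    config: SimulationConfig,
) -> SimulationResult:
    """Run the inner Monte Carlo loop at fixed occurrence rate.

    Per iteration: draw the occurrence count; for each occurrence draw a
    causal category and a victim count; score every victim's injuries and
    accumulate their DALYs into the occurrence's cause bucket.  Victimless
    occurrences contribute zero but are counted.
    """
    tables = _SamplingTables(dists, catalogue, life, config)
    iterations = tuple(
        _run_iteration(
            rate.lam,
            tables,
            config,
            _child_rng(config.seed, 0, i),
            outer_index=0,
            bias=rate.bias,
        )
        for i in range(config.iterations)
    )
    return SimulationResult(iterations, config, dists, rate)


def run_second_order(
    rate: RateEstimate,
    dists: EmpiricalDistributions,
    catalogue: InjuryCatalogue,
    life: RemainingLifeModel,
    config: SimulationConfig,
) -> SimulationResult:
    """Run the outer uncertainty loop over the reporting-bias multiplier.

    Each outer draw samples a bias, recomputes the rate from the same
    count ingredients, and runs the full first-order loop.  With a
    point-mass bias distribution and one outer draw this reproduces
    :func:`run_first_order` bit-exactly.
    """
    all_iterations: list[IterationResult] = []
    for o in range(config.outer_iterations):
        bias_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 0x0B1A5, o))
        )
        bias = config.bias_distribution.sample(bias_rng)
        rate_o = rate.with_bias(bias)
        tables = _SamplingTables(dists, catalogue, life, config)
        for i in range(config.iterations):
            all_iterations.append(
                _run_iteration(
                    rate_o.lam,
                    tables,
                    config,
                    _child_rng(config.seed, o, i),
                    outer_index=o,
                    bias=bias,
                )
            )
    return SimulationResult(tuple(all_iterations), config, dists, rate)


def write_results(result: SimulationResult, path: str | Path) -> None:
    """Serialize one row per iteration to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "outer_index", "bias", "n_occurrences", "n_victims",
             "n_fatalities", *CAUSES, "total_dalys"]
        )
        for i, it in enumerate(result.iterations):
            writer.writerow(
                [i, it.outer_index, it.bias, it.n_occurrences, it.n_victims,
                 it.n_fatalities]
                + [it.dalys_by_cause[c] for c in CAUSES]
                + [it.total_dalys]
            )
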