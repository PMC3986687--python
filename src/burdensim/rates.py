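"""Mean occurrence-rate estimation from incident and near-miss counts.

The rate feeding the Poisson occurrence process is

    lambda = bias * (n_i + n_m / r) / T    [occurrences / year]

where ``n_i`` is the incident count, ``n_m`` the near-miss count, ``T``
the observed duration in years, ``r`` the assumed near-miss-to-incident
ratio, and ``bias`` a reporting-bias multiplier (>= 1) for occurrences
that go unreported.  ``r = 1`` is the conservative reporting convention in
which every near miss counts fully toward the rate; larger ``r``
down-weights near misses per the industrial safety-pyramid rule.  The
rate is assumed constant over the prediction horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RateEstimate", "estimate_rate", "rate_per_million"]


@dataclass(frozen=True)
class RateEstimate:
    """An occurrence rate together with the ingredients that produced it."""

    n_i: int
    n_m: int
    r: float
    T: float
    bias: float
    lam: float

    def with_bias(self, bias: float) -> "RateEstimate":
        """Recompute the rate under a different reporting-bias multiplier."""
        return estimate_rate(self.n_i, self.n_m, self.r, self.T, bias)


def estimate_rate(
    n_i: int, n_m: int, r: float = 1.0, T: float = 1.0, bias: float = 1.0
) -> RateEstimate:
    """Estimate the mean occurrence rate (occurrences/year).

    Parameters
    ----------
    n_i, n_m
        Non-negative incident and near-miss counts over the observation
        window.
    r
        Near-miss-to-incident ratio, >= 1.
    T
        Observed duration in years, > 0.
    bias
        Reporting-bias multiplier, >= 1 (1 = no unreported occurrences).
    """
    if n_i < 0 or n_m < 0:
        raise ValueError("counts must be non-negative")
    if int(n_i) != n_i or int(n_m) != n_m:
        raise ValueError("counts must be integers")
    if T <= 0:
        raise ValueError(f"observed duration T must be > 0, got {T}")
    if r < 1:
        raise ValueError(f"near-miss ratio r must be >= 1, got {r}")
    if bias < 1:
        raise ValueError(f"reporting-bias multiplier must be >= 1, got {bias}")
    lam = bias * (n_i + n_m / r) / T
    return RateEstimate(n_i=int(n_i), n_m=int(n_m), r=r, T=T, bias=bias, lam=lam)


def rate_per_million(est: RateEstimate, population: float) -> float:
    """Occurrence rate normalised per million exposed persons per year."""
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return est.lam / (population / 1e6)
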