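"""Holey-landscape / Dobzhansky-Muller incompatibility arithmetic.

Two isolated populations accumulate substitutions; each substitution has a
probability ``epsilon`` of being incompatible with an earlier derived
allele (a "hole" in the otherwise-neutral genotype landscape).  Under
pairwise counting the expected number of incompatibilities after ``d``
substitutions is ``epsilon * d``; under all-pairs (snowball) counting it is
``epsilon * d (d - 1) / 2`` and grows quadratically.  With any single
incompatible pair causing complete reproductive isolation, the number of
substitutions to RI is geometric with success probability ``epsilon``
(mean ``1 / epsilon``), and the expected time to RI is that mean divided by
the per-pair substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LandscapeModel",
    "RIWaitingTime",
    "incompatibility_count",
    "expected_paths",
    "snowball_condition",
    "interbreed_probability",
    "RISubstitutionDistribution",
    "ri_substitution_distribution",
    "expected_time_to_ri",
    "fit_epsilon_and_exponent",
]

ACCUMULATION_MODES = ("pairwise_linear", "snowball_quadratic")


@dataclass(frozen=True)
class LandscapeModel:
    """Mutational-target count L, hole probability epsilon, counting mode."""

    big_l: int
    epsilon: float
    accumulation: str = "pairwise_linear"

    def __post_init__(self) -> None:
        if self.big_l < 1:
            raise ValueError(f"big_l must be >= 1, got {self.big_l}")
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if self.accumulation not in ACCUMULATION_MODES:
            raise ValueError(f"unknown accumulation mode {self.accumulation!r}")


@dataclass(frozen=True)
class RIWaitingTime:
    """Substitution count at which RI completes and the implied time."""

    k_substitutions: int
    time_generations: float

    def __post_init__(self) -> None:
        if self.k_substitutions < 1:
            raise ValueError("k_substitutions must be >= 1")
        if not self.time_generations > 0:
            raise ValueError("time_generations must be > 0")


def incompatibility_count(d: float, model: LandscapeModel) -> float:
    """Expected incompatibilities between populations d substitutions apart."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if model.accumulation == "pairwise_linear":
        return model.epsilon * d
    return model.epsilon * d * (d - 1) / 2.0


def expected_paths(model: LandscapeModel) -> tuple[float, bool]:
    """Expected viable one-substitution steps L(1 - epsilon) and whether > 1."""
    n_paths = model.big_l * (1.0 - model.epsilon)
    return n_paths, n_paths > 1.0


def snowball_condition(model: LandscapeModel) -> bool:
    """True when epsilon < ln(L)/L, the quadratic-accumulation condition."""
    if model.big_l < 2:
        raise ValueError("snowball condition requires big_l >= 2")
    return model.epsilon < np.log(model.big_l) / model.big_l


def interbreed_probability(d: float, epsilon: float) -> float:
    """Probability (1 - epsilon)^d that d substitutions leave no hole."""
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    return (1.0 - epsilon) ** d


class RISubstitutionDistribution:
    """Geometric law of the substitution index k at which RI completes.

    pmf(k) = (1 - epsilon)^(k-1) epsilon for k >= 1; mean 1/epsilon.
    """

    def __init__(self, epsilon: float):
        if not (0.0 < epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
        self.epsilon = epsilon
        self._geom = stats.geom(epsilon)

    @property
    def mean(self) -> float:
        return 1.0 / self.epsilon

    def pmf(self, k):
        return self._geom.pmf(k)

    def cdf(self, k):
        return self._geom.cdf(k)

    def sf(self, k):
        """Survival P(K > k) = (1 - epsilon)^k, the interbreeding probability."""
        return self._geom.sf(k)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.geometric(self.epsilon, size=size)


def ri_substitution_distribution(epsilon: float) -> RISubstitutionDistribution:
    """Distribution of the number of substitutions required to reach RI."""
    return RISubstitutionDistribution(epsilon)


def expected_time_to_ri(epsilon: float, substitution_rate: float) -> float:
    """Expected generations to complete RI: (1/epsilon) / substitution_rate."""
    if not (0.0 < epsilon < 1.0):
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    if substitution_rate <= 0:
        raise ValueError(f"substitution_rate must be > 0, got {substitution_rate}")
    return (1.0 / epsilon) / substitution_rate


def fit_epsilon_and_exponent(
    table: pd.DataFrame, accumulation: str = "pairwise_linear"
) -> tuple[float, float]:
    """Estimate (epsilon, growth exponent) from (d, incompatibility count) rows.

    Fits ``count = a * d^b`` by ordinary least squares on the log-log scale,
    dropping zero-count rows (they have no log image).  The epsilon estimate
    reads ``a`` through the declared accumulation model: ``a = epsilon`` for
    pairwise counting and ``a = epsilon / 2`` for snowball (all-pairs)
    counting, whose large-d count is ``(epsilon/2) d^2``.

    Parameters
    ----------
    table : DataFrame with columns ``d`` and ``count``.
    accumulation : {"pairwise_linear", "snowball_quadratic"}

    Returns
    -------
    (epsilon_hat, exponent_hat)
    """
    if accumulation not in ACCUMULATION_MODES:
        raise ValueError(f"unknown accumulation mode {accumulation!r}")
    missing = {"d", "count"} - set(table.columns)
    if missing:
        raise ValueError(f"table is missing column(s): {sorted(missing)}")
    d = np.asarray(table["d"], dtype=float)
    c = np.asarray(table["count"], dtype=float)
    if np.any(d < 1):
        raise ValueError("all d values must be >= 1")
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    if not np.any(c > 0):
        raise ValueError("unfittable: all counts are zero")
    keep = c > 0
    if keep.sum() < 3:
        raise ValueError("insufficient data: fewer than 3 positive-count rows")
    slope, intercept = np.polyfit(np.log(d[keep]), np.log(c[keep]), 1)
    a = float(np.exp(intercept))
    epsilon_hat = a if accumulation == "pairwise_linear" else 2.0 * a
    return epsilon_hat, float(slope)
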