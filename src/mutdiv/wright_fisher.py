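"""Fixation probabilities and substitution rates under changing population size.

The model is a discrete Wright-Fisher population of ``2N`` gene copies with
genic selection: a derived allele at frequency ``x`` with selection
coefficient ``s`` is sampled into the next generation of size ``2N'`` with
per-copy probability ``x (1 + s) / (1 + x s)``.

The fixation probability of a mutation arising just before a deterministic
size change of length ``T`` generations is

    P_fix = (1 - E[exp(-4 Ne s X(T))]) / (1 - exp(-4 Ne s)),

where ``Ne`` is the (post-change, final) effective size and ``X(T)`` the
allele frequency after the change.  The expectation is taken over
Wright-Fisher replicates; at ``T = 0`` (constant size) the expression
collapses to Kimura's closed form

    P_fix = (1 - exp(-4 Ne s x0)) / (1 - exp(-4 Ne s)),

and in the neutral limit ``s -> 0`` to ``P_fix = E[X(T)]`` (= ``x0`` by the
martingale property).  The long-run substitution rate is the number of new
mutations per generation times the fixation probability, ``2 Ne u P_fix``,
which for neutral mutations reduces to ``u Ne / N`` regardless of
demographic history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographyProfile, build_size_trajectory, standard_scenarios

__all__ = [
    "NEUTRAL",
    "SLIGHTLY_DELETERIOUS",
    "DELETERIOUS",
    "BENEFICIAL",
    "FixationEstimate",
    "RatePrediction",
    "wf_step",
    "simulate_trajectory",
    "simulate_frequency_at_T",
    "fixation_fraction_to_absorption",
    "fixation_probability",
    "exact_matrix_fixation",
    "kimura_fixation",
    "substitution_rate",
    "dnds_ratio",
    "krkc_ratio",
    "scenario_grid",
]

# Named selection classes for the substitution-rate grid.
NEUTRAL = 0.0
SLIGHTLY_DELETERIOUS = -0.001
DELETERIOUS = -0.01
BENEFICIAL = +0.001


def _check_s(s: float) -> None:
    if s <= -1.0:
        raise ValueError(f"selection coefficient must exceed -1, got {s}")


@dataclass(frozen=True)
class FixationEstimate:
    """Fixation probability with Monte-Carlo error and provenance tag."""

    p_fix: float
    std_error: float
    n_replicates: int
    method: str  # analytic_kimura | neutral_limit | monte_carlo | matrix_exact

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fix <= 1.0):
            raise ValueError(f"p_fix out of [0, 1]: {self.p_fix}")
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


@dataclass(frozen=True)
class RatePrediction:
    """Substitution rate implied by a mutation rate and a fixation estimate."""

    mutation_rate: float
    substitution_rate: float
    log_ratio: float  # ln(substitution_rate / mutation_rate); nan if rate is 0


def wf_step(x: float, s: float, n_next: int, rng: np.random.Generator) -> float:
    """One Wright-Fisher generation: binomial resampling with genic selection.

    Returns ``j / (2 n_next)`` with ``j ~ Binomial(2 n_next, x(1+s)/(1+xs))``.
    Frequencies 0 and 1 are absorbing.
    """
    _check_s(s)
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"frequency out of [0, 1]: {x}")
    if n_next < 2:
        raise ValueError(f"population size must be >= 2, got {n_next}")
    if x == 0.0 or x == 1.0:
        return x
    p = x * (1.0 + s) / (1.0 + x * s)
    return rng.binomial(2 * n_next, p) / (2 * n_next)


def _step_array(x: np.ndarray, s: float, n_next: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised ``wf_step`` over a replicate array (absorption preserved)."""
    p = x * (1.0 + s) / (1.0 + x * s)
    return rng.binomial(2 * n_next, p) / (2.0 * n_next)


def simulate_trajectory(
    x0: float,
    s: float,
    profile: DemographyProfile,
    horizon: int,
    rng: np.random.Generator,
    replicate_id: int = 0,
):
    """Single allele-frequency trajectory over ``horizon`` generations.

    Returns ``(frequencies, replicate_id, absorbed)`` where ``absorbed`` is
    one of ``"lost"``, ``"fixed"`` or ``"segregating"``.
    """
    sizes = build_size_trajectory(profile, horizon)
    freqs = np.empty(horizon + 1)
    freqs[0] = x0
    x = x0
    for g in range(1, horizon + 1):
        x = wf_step(x, s, int(sizes[g]), rng)
        freqs[g] = x
    absorbed = "lost" if x == 0.0 else ("fixed" if x == 1.0 else "segregating")
    return freqs, replicate_id, absorbed


def simulate_frequency_at_T(
    x0: float,
    s: float,
    profile: DemographyProfile,
    n_replicates: int,
    seed: int | np.random.Generator | np.random.SeedSequence,
    horizon: int | None = None,
) -> np.ndarray:
    """Replicate allele frequencies after the size change (X(T) samples).

    Simulates ``n_replicates`` independent Wright-Fisher paths from initial
    frequency ``x0`` through generation ``T = profile.duration`` (or
    ``horizon`` if given) and returns the final frequencies.
    """
    _check_s(s)
    if not (0.0 < x0 < 1.0):
        raise ValueError(f"initial frequency must be in (0, 1), got {x0}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    T = profile.duration if horizon is None else horizon
    rng = np.random.default_rng(seed)
    sizes = build_size_trajectory(profile, T)
    x = np.full(n_replicates, x0)
    for g in range(1, T + 1):
        x = _step_array(x, s, int(sizes[g]), rng)
    return x


def fixation_fraction_to_absorption(
    x0: float,
    s: float,
    profile: DemographyProfile,
    n_replicates: int,
    seed,
    max_generations: int = 2_000_000,
) -> FixationEstimate:
    """Monte-Carlo fixation probability by running every replicate to 0 or 1.

    The demographic change plays out first; thereafter the population stays
    at its final size.  The standard error is the binomial SE of the fixed
    fraction.
    """
    _check_s(s)
    if not (0.0 < x0 < 1.0):
        raise ValueError(f"initial frequency must be in (0, 1), got {x0}")
    rng = np.random.default_rng(seed)
    sizes = build_size_trajectory(profile, profile.duration)
    n_final = profile.final_size
    x = np.full(n_replicates, x0)
    fixed = 0
    for g in range(1, max_generations + 1):
        n_now = int(sizes[g]) if g <= profile.duration else n_final
        x = _step_array(x, s, n_now, rng)
        fixed += int(np.count_nonzero(x == 1.0))
        x = x[(x > 0.0) & (x < 1.0)]
        if x.size == 0:
            break
    else:
        raise RuntimeError("replicates failed to absorb within max_generations")
    p = fixed / n_replicates
    se = float(np.sqrt(p * (1.0 - p) / n_replicates))
    return FixationEstimate(p, se, n_replicates, "monte_carlo")


def kimura_fixation(ne: float, s: float, x0: float) -> float:
    """Kimura's constant-size closed form (1-e^(-4 Ne s x0))/(1-e^(-4 Ne s))."""
    _check_s(s)
    if s == 0.0:
        return x0
    # expm1 keeps the ratio accurate when 4*Ne*s*x0 is tiny.
    return float(np.expm1(-4.0 * ne * s * x0) / np.expm1(-4.0 * ne * s))


def fixation_probability(
    s: float,
    profile: DemographyProfile,
    x0: float | None = None,
    n_replicates: int = 500_000,
    seed=None,
    horizon: int | None = None,
) -> FixationEstimate:
    """Fixation probability of a new mutation under the given demography.

    For constant-size profiles (and default horizon) the analytic branch
    returns Kimura's closed form with zero error.  Otherwise ``n_replicates``
    Wright-Fisher paths supply X(T) samples; the estimator is the replicate
    mean of ``(1 - e^(-4 Ne_final s X(T))) / (1 - e^(-4 Ne_final s))`` for
    ``s != 0`` and of ``X(T)`` in the neutral limit, with the delta-method
    standard error of the mean.

    ``x0`` defaults to a new mutation's frequency ``1 / (2 n0)``.
    """
    _check_s(s)
    if x0 is None:
        x0 = 1.0 / (2 * profile.n0)
    if not (0.0 < x0 < 1.0):
        raise ValueError(f"initial frequency must be in (0, 1), got {x0}")

    analytic_ok = profile.is_constant and horizon is None
    if analytic_ok:
        if s == 0.0:
            return FixationEstimate(x0, 0.0, 0, "neutral_limit")
        return FixationEstimate(kimura_fixation(profile.ne_final, s, x0), 0.0, 0, "analytic_kimura")

    xT = simulate_frequency_at_T(x0, s, profile, n_replicates, seed, horizon=horizon)
    if s == 0.0:
        p = float(np.mean(xT))
        se = float(np.std(xT, ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else 0.0
        return FixationEstimate(p, se, n_replicates, "neutral_limit")
    ne_final = profile.ne_final
    # per-replicate Kimura transform; its mean is the general-formula Pfix
    vals = np.expm1(-4.0 * ne_final * s * xT) / np.expm1(-4.0 * ne_final * s)
    p = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    p = min(max(p, 0.0), 1.0)
    return FixationEstimate(p, se, n_replicates, "monte_carlo")


def exact_matrix_fixation(n: int, s: float, x0: float) -> FixationEstimate:
    """Exact fixation probability of the 2n+1-state absorbing Markov chain.

    Solves the linear system for the chain on allele counts 0..2n with the
    same binomial/genic-selection kernel as :func:`wf_step`.  ``x0`` must be
    a lattice point j/(2n).  Intended as a small-population oracle
    (``2n <= 200``).
    """
    _check_s(s)
    two_n = 2 * n
    if two_n > 200:
        raise ValueError(f"2n = {two_n} exceeds the dense-matrix limit of 200")
    j0 = x0 * two_n
    if abs(j0 - round(j0)) > 1e-9:
        raise ValueError(f"x0 = {x0} is not a lattice point j/(2n) for 2n = {two_n}")
    j0 = int(round(j0))
    if j0 == 0:
        return FixationEstimate(0.0, 0.0, 0, "matrix_exact")
    if j0 == two_n:
        return FixationEstimate(1.0, 0.0, 0, "matrix_exact")

    from scipy.stats import binom

    i = np.arange(1, two_n)  # transient states
    x = i / two_n
    p_sel = x * (1.0 + s) / (1.0 + x * s)
    # full transition rows for transient states over columns 0..2n
    P = binom.pmf(np.arange(two_n + 1)[None, :], two_n, p_sel[:, None])
    Q = P[:, 1:two_n]
    b = P[:, two_n]
    h = np.linalg.solve(np.eye(two_n - 1) - Q, b)
    p = float(np.clip(h[j0 - 1], 0.0, 1.0))
    return FixationEstimate(p, 0.0, 0, "matrix_exact")


def substitution_rate(
    u: float, profile: DemographyProfile, p: FixationEstimate
) -> RatePrediction:
    """Long-run substitution rate 2 Ne u P_fix at the mutation's origin.

    ``Ne`` is the effective size when the mutation arises
    (``ne_over_n * n0``), so the neutral rate equals ``u Ne / N`` — and
    exactly ``u`` when Ne = N — under every demographic scenario.
    """
    if u <= 0:
        raise ValueError(f"mutation rate must be > 0, got {u}")
    rate = 2.0 * profile.ne_initial * u * p.p_fix
    log_ratio = float(np.log(rate / u)) if rate > 0 else float("nan")
    return RatePrediction(u, rate, log_ratio)


def _ratio_of_fixation(
    s_num: float,
    s_den: float,
    profile: DemographyProfile,
    n_replicates: int,
    seed,
) -> float:
    x0 = 1.0 / (2 * profile.n0)
    if profile.is_constant:
        num = fixation_probability(s_num, profile, x0)
        den = fixation_probability(s_den, profile, x0)
    else:
        ss = np.random.SeedSequence(seed)
        s1, s2 = ss.spawn(2)
        num = fixation_probability(s_num, profile, x0, n_replicates, s1)
        den = fixation_probability(s_den, profile, x0, n_replicates, s2)
    if den.p_fix == 0:
        return float("nan")
    return num.p_fix / den.p_fix


def dnds_ratio(profile: DemographyProfile, n_replicates: int = 500_000, seed=None) -> float:
    """dN/dS proxy: P_fix(s = -0.001) / P_fix(s = 0), same demography."""
    return _ratio_of_fixation(SLIGHTLY_DELETERIOUS, NEUTRAL, profile, n_replicates, seed)


def krkc_ratio(profile: DemographyProfile, n_replicates: int = 500_000, seed=None) -> float:
    """Kr/Kc proxy: P_fix(s = -0.01) / P_fix(s = -0.001), same demography."""
    return _ratio_of_fixation(DELETERIOUS, SLIGHTLY_DELETERIOUS, profile, n_replicates, seed)


_SCENARIO_PARAMS = {
    "constant": (1.0, 0),
    "fast_growth": (1.9, 20),
    "slow_growth": (1.9, 200),
    "fast_decline": (0.1, 20),
    "slow_decline": (0.1, 200),
}


def scenario_grid(
    ne_values=(500, 1000, 5000),
    scenarios=("constant", "fast_growth", "slow_growth", "fast_decline", "slow_decline"),
    s_values=(NEUTRAL, BENEFICIAL, SLIGHTLY_DELETERIOUS, DELETERIOUS),
    n_replicates: int = 500_000,
    seed: int = 0,
    ne_over_n: float = 1.0,
) -> pd.DataFrame:
    """Substitution-rate grid over demographic scenarios, Ne and s classes.

    One row per (scenario, initial Ne, s) with the Monte-Carlo fixation
    probability, its standard error, the log substitution-rate-to-mutation-
    rate ratio, and the dN/dS and Kr/Kc fixation-probability ratios for
    that (scenario, Ne) cell.  Each cell draws from an independent random
    stream derived from ``seed`` by spawn keys, so any sub-grid is
    reproducible in isolation.
    """
    rows = []
    for si, scen in enumerate(scenarios):
        ratio, duration = _SCENARIO_PARAMS[scen]
        for ni, ne in enumerate(ne_values):
            n0 = int(round(ne / ne_over_n))
            profile = DemographyProfile(n0, ratio, duration, ne_over_n=ne_over_n)
            x0 = 1.0 / (2 * n0)
            cell: dict[float, FixationEstimate] = {}
            for ki, s in enumerate(s_values):
                ss = np.random.SeedSequence(seed, spawn_key=(si, ni, ki))
                if profile.is_constant:
                    cell[s] = fixation_probability(s, profile, x0)
                else:
                    cell[s] = fixation_probability(s, profile, x0, n_replicates, ss)
            # ratios need both classes even if not in s_values
            def _p(s_val: float, key: int) -> FixationEstimate:
                if s_val in cell:
                    return cell[s_val]
                ss = np.random.SeedSequence(seed, spawn_key=(si, ni, 100 + key))
                if profile.is_constant:
                    return fixation_probability(s_val, profile, x0)
                return fixation_probability(s_val, profile, x0, n_replicates, ss)

            p_neu = _p(NEUTRAL, 0)
            p_sld = _p(SLIGHTLY_DELETERIOUS, 1)
            p_del = _p(DELETERIOUS, 2)
            dnds = p_sld.p_fix / p_neu.p_fix if p_neu.p_fix > 0 else float("nan")
            krkc = p_del.p_fix / p_sld.p_fix if p_sld.p_fix > 0 else float("nan")
            for s in s_values:
                est = cell[s]
                # log ratio is u-free: ln(2 * Ne_initial * p_fix)
                lr = (
                    float(np.log(2.0 * profile.ne_initial * est.p_fix))
                    if est.p_fix > 0
                    else float("nan")
                )
                se_lr = est.std_error / est.p_fix if est.p_fix > 0 else float("nan")
                rows.append(
                    {
                        "scenario": scen,
                        "ne": ne,
                        "ne_final": profile.ne_final,
                        "s": s,
                        "p_fix": est.p_fix,
                        "se": est.std_error,
                        "substitution_log_ratio": lr,
                        "se_log_ratio": se_lr,
                        "dnds": dnds,
                        "krkc": krkc,
                    }
                )
    return pd.DataFrame(rows)
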