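"""Deterministic census-size trajectories for Wright-Fisher simulation.

A :class:`DemographyProfile` describes a diploid population whose census
size changes deterministically from ``n0`` to ``round(n0 * ratio)`` over
``duration`` generations (linearly or exponentially interpolated) and then
stays constant.  The effective size is tied to the census size through the
``ne_over_n`` ratio, so Ne tracks N throughout the size change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DemographyProfile", "build_size_trajectory", "standard_scenarios"]


@dataclass(frozen=True)
class DemographyProfile:
    """Deterministic size-change trajectory plus the Ne/N convention.

    Parameters
    ----------
    n0 : int
        Census number of diploid individuals at generation 0 (>= 2).
    ratio : float
        Final size divided by initial size (> 0); 1.0 means constant size.
    duration : int
        Number of generations over which the size change unfolds (>= 0).
        From generation ``duration`` onward the size is constant at
        ``round(n0 * ratio)``.
    shape : {"linear", "exponential"}
        Interpolation of the census size between the endpoints.
    ne_over_n : float
        Ratio of effective to census size (default 1).
    """

    n0: int
    ratio: float = 1.0
    duration: int = 0
    shape: str = "linear"
    ne_over_n: float = 1.0

    def __post_init__(self) -> None:
        if self.n0 < 2:
            raise ValueError(f"n0 must be >= 2, got {self.n0}")
        if not self.ratio > 0:
            raise ValueError(f"ratio must be > 0, got {self.ratio}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.shape not in ("linear", "exponential"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not self.ne_over_n > 0:
            raise ValueError(f"ne_over_n must be > 0, got {self.ne_over_n}")
        if self.final_size < 2:
            raise ValueError(
                f"degenerate demography: final size {self.final_size} < 2"
            )

    @property
    def final_size(self) -> int:
        """Census size at and after generation ``duration``."""
        return int(round(self.n0 * self.ratio))

    @property
    def ne_initial(self) -> float:
        return self.ne_over_n * self.n0

    @property
    def ne_final(self) -> float:
        return self.ne_over_n * self.final_size

    @property
    def is_constant(self) -> bool:
        return self.duration == 0 or self.final_size == self.n0


def build_size_trajectory(profile: DemographyProfile, horizon: int) -> np.ndarray:
    """Census size per generation, from generation 0 through ``horizon``.

    Returns an integer array of length ``horizon + 1``; element ``g`` is the
    census size during generation ``g``.  Sizes are rounded to the nearest
    integer; a trajectory that dips below 2 individuals is rejected.
    """
    if horizon < profile.duration:
        raise ValueError(
            f"horizon {horizon} shorter than profile duration {profile.duration}"
        )
    d = profile.duration
    sizes = np.empty(horizon + 1, dtype=np.int64)
    if d == 0:
        sizes[:] = profile.n0
        sizes[0] = profile.n0
    else:
        g = np.arange(d + 1)
        if profile.shape == "linear":
            raw = profile.n0 + (profile.final_size - profile.n0) * g / d
        else:  # exponential
            raw = profile.n0 * (profile.final_size / profile.n0) ** (g / d)
        sizes[: d + 1] = np.round(raw).astype(np.int64)
        sizes[d:] = profile.final_size
    if np.any(sizes < 2):
        raise ValueError("degenerate demography: interpolated size < 2")
    return sizes


def standard_scenarios(n0: int = 1000, ne_over_n: float = 1.0) -> dict[str, DemographyProfile]:
    """The five demographic scenarios used in the rate-ratio grid.

    Growth ends at 1.9x the initial size, decline at 0.1x; fast change
    takes 20 generations and slow change takes 200.
    """
    return {
        "constant": DemographyProfile(n0, 1.0, 0, ne_over_n=ne_over_n),
        "fast_growth": DemographyProfile(n0, 1.9, 20, ne_over_n=ne_over_n),
        "slow_growth": DemographyProfile(n0, 1.9, 200, ne_over_n=ne_over_n),
        "fast_decline": DemographyProfile(n0, 0.1, 20, ne_over_n=ne_over_n),
        "slow_decline": DemographyProfile(n0, 0.1, 200, ne_over_n=ne_over_n),
    }
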