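"""Synthetic inputs: incompatibility tables and canned regime configurations.

The table generator emulates the observable a hybrid-incompatibility survey
would produce: for each divergence level ``d`` (substitutions separating a
species pair) an incompatibility count, either the exact model expectation
(noiseless) or a Poisson draw around it.  It does not emulate divergence-
estimation error or ascertainment bias in which pairs get surveyed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import LandscapeModel, incompatibility_count

__all__ = ["make_incompatibility_table", "regime_suite", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("pairwise_table", "snowball_table", "regime_suite")


def make_incompatibility_table(
    epsilon: float,
    d_values,
    accumulation: str = "pairwise_linear",
    noise: str = "none",
    seed=None,
) -> pd.DataFrame:
    """(d, count) table under the chosen accumulation model.

    ``noise="none"`` writes the exact expected counts; ``noise="poisson"``
    draws each count from a Poisson law with that expectation.
    """
    model = LandscapeModel(big_l=1000, epsilon=epsilon, accumulation=accumulation)
    d = np.asarray(list(d_values), dtype=int)
    mu = np.array([incompatibility_count(int(x), model) for x in d], dtype=float)
    if noise == "none":
        counts = mu
    elif noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mu).astype(float)
    else:
        raise ValueError(f"unknown noise mode {noise!r}")
    return pd.DataFrame({"d": d, "count": counts})


def regime_suite() -> dict[str, dict]:
    """Canned T_I/T_S/T_R parameter sets, one per diversification regime."""
    return {
        "isolation_completes_ri": {
            "t_i": 100.0, "t_s": 500.0, "t_r": 200.0,
            "timing_mode": "fixed", "total_time": 350.0,
        },
        "fusion_latest_split_only": {
            "t_i": 100.0, "t_s": 30.0, "t_r": 5000.0,
            "timing_mode": "fixed", "total_time": 500.0,
        },
        "chained_isolation": {
            "t_i": 30.0, "t_s": 50.0, "t_r": 5000.0,
            "timing_mode": "exponential", "total_time": 200.0,
        },
        "partial_ri_contact": {
            "t_i": 100.0, "t_s": 80.0, "t_r": 300.0,
            "timing_mode": "exponential", "total_time": 600.0,
        },
    }
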