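"""Statistical power for binary-outcome summary-data MR.

Implements the non-centrality approximation used by the mRnd online
calculator: with a combined outcome sample of n, case fraction p, total
instrument variance explained R²(X|Z), and hypothesized odds ratio OR,

    power = Φ( |ln OR| · √(n · R² · p(1−p)) − z_{1−α/2} ).

The inverse problem — the smallest detectable OR at a target power — is
solved by monotone root-finding on ln OR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import optimize, stats

__all__ = ["PowerInput", "mr_power_binary", "minimum_detectable_or"]


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome power approximation.

    n_total: combined cases + controls; prop_case: case fraction in
    (0,1); r2_xz: instrument variance explained in (0,1); odds_ratio:
    hypothesized OR per SD of exposure; alpha: two-sided level.
    """

    n_total: float
    prop_case: float
    r2_xz: float
    odds_ratio: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0.0 < self.prop_case < 1.0):
            raise ValueError("prop_case must be in (0, 1)")
        if not (0.0 < self.r2_xz < 1.0):
            raise ValueError("r2_xz must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def mr_power_binary(input: PowerInput) -> tuple[float, int]:
    """Power as a proportion and as a rounded percent.

    At OR = 1 the formula returns the one-tail α/2 rejection probability
    (0.025 at α = 0.05); power increases monotonically with n, R²,
    |ln OR| and case balance.
    """
    z = stats.norm.ppf(1.0 - input.alpha / 2.0)
    ncp = abs(math.log(input.odds_ratio)) * math.sqrt(
        input.n_total * input.r2_xz * input.prop_case * (1.0 - input.prop_case)
    )
    power = float(stats.norm.cdf(ncp - z))
    return power, round(100.0 * power)


def minimum_detectable_or(
    input: PowerInput, target_power: float, rel_tol: float = 1e-6
) -> float:
    """Smallest OR > 1 with power ≥ ``target_power``.

    Requires target_power in (α/2·2-tail floor, 1); solved by bisection
    on ln OR to the requested relative tolerance.
    """
    floor, _ = mr_power_binary(replace(input, odds_ratio=1.0))
    if not (floor < target_power < 1.0):
        raise ValueError(f"target_power must be in ({floor:.4g}, 1)")

    def gap(log_or: float) -> float:
        p, _ = mr_power_binary(replace(input, odds_ratio=math.exp(log_or)))
        return p - target_power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("could not bracket the minimum detectable OR")
    log_or = optimize.brentq(gap, 1e-12, hi, rtol=rel_tol)
    return math.exp(log_or)
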