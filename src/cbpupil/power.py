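"""Simulation-based and analytic power for paired t-tests.

A paired design with n subjects and standardized effect size d (Cohen's d
for paired differences) is simulated by drawing n differences from
Normal(d, 1) and applying a one-sample t-test.  The analytic companion
uses the noncentral t distribution with df = n-1 and noncentrality
ncp = d*sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PowerResult:
    n: int
    d: float
    alpha: float
    sided: str
    reps: int
    power: float
    mc_se: float
    analytic_power: float


def analytic_power_paired_t(n: int, d: float, alpha: float = 0.05,
                            sided: str = "one") -> float:
    """Closed-form power via the noncentral t distribution."""
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    ncp = d * np.sqrt(n)
    if sided == "one":
        tc = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tc, df, ncp))
    if sided == "two":
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))
    raise ValueError(f"unknown sidedness {sided!r}")


def simulate_power(n: int, d: float, alpha: float = 0.05, sided: str = "one",
                   reps: int = 20000, seed: int = 0) -> PowerResult:
    """Monte-Carlo rejection rate of the paired t-test."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(d, 1.0, size=(reps, n))
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
    df = n - 1
    if sided == "one":
        reject = t > stats.t.ppf(1 - alpha, df)
    elif sided == "two":
        reject = np.abs(t) > stats.t.ppf(1 - alpha / 2, df)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    p = float(reject.mean())
    return PowerResult(
        n=n, d=d, alpha=alpha, sided=sided, reps=reps, power=p,
        mc_se=float(np.sqrt(p * (1 - p) / reps)),
        analytic_power=analytic_power_paired_t(n, d, alpha, sided))
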