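"""ICC-based study sizing.

Answers the planning question behind a reliability study: how many subjects
are needed to demonstrate, at level alpha with a given power, that the ICC
exceeds a null value p0 when the true ICC is p1?

The calculation uses the asymptotic method implemented by the standard ICC
sample-size calculators (Zou's formula): the transformation

    g(p) = ln(1 + k·p / (1 - p))

of the ICC is approximately normal with variance 2k / ((k-1)(n-1)), so the
achieved power of the one-sided level-alpha test of H0: ICC = p0 against
ICC = p1 is

    power(n) = Phi( |g(p1) - g(p0)| · sqrt((k-1)(n-1)/(2k)) - z_alpha )

and the sample size is the smallest n meeting the target power, equivalent
to the closed form n = 1 + 2k(z_a + z_b)^2 / ((k-1)·(g(p1) - g(p0))^2).
A two-sided variant replaces z_alpha by z_{alpha/2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

__all__ = ["PowerSpec", "icc_power", "icc_sample_size", "power_curve"]


@dataclass(frozen=True)
class PowerSpec:
    """Hypotheses and operating characteristics for ICC study sizing."""

    p0: float
    p1: float
    alpha: float = 0.05
    power: float = 0.9
    k: int = 2
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < self.p1 < 1.0:
            raise ValueError("need 0 <= p0 < p1 < 1")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.5 < self.power < 1.0:
            raise ValueError("power must lie in (0.5, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2 raters")


def _g(p: float, k: int) -> float:
    return math.log(1.0 + k * p / (1.0 - p))


def icc_power(n: int, spec: PowerSpec) -> float:
    """Achieved power of the ICC test at ``n`` subjects."""
    if n < spec.k + 1:
        raise ValueError(f"n must be >= k + 1 = {spec.k + 1}")
    z_a = stats.norm.ppf(
        1.0 - (spec.alpha / 2.0 if spec.two_sided else spec.alpha)
    )
    delta = abs(_g(spec.p1, spec.k) - _g(spec.p0, spec.k))
    scale = math.sqrt((spec.k - 1) * (n - 1) / (2.0 * spec.k))
    return float(stats.norm.cdf(delta * scale - z_a))


def icc_sample_size(spec: PowerSpec) -> int:
    """Smallest subject count achieving the target power.

    Starts at the closed-form solution and scans to enforce minimality:
    power(n) >= target and power(n - 1) < target (down to the floor k + 1).
    """
    z_a = stats.norm.ppf(
        1.0 - (spec.alpha / 2.0 if spec.two_sided else spec.alpha)
    )
    z_b = stats.norm.ppf(spec.power)
    delta = abs(_g(spec.p1, spec.k) - _g(spec.p0, spec.k))
    n = 1.0 + 2.0 * spec.k * (z_a + z_b) ** 2 / ((spec.k - 1) * delta**2)
    n = max(spec.k + 1, math.ceil(n - 1e-9))
    while n > spec.k + 1 and icc_power(n - 1, spec) >= spec.power:
        n -= 1
    while icc_power(n, spec) < spec.power:
        n += 1
    return int(n)


def power_curve(spec: PowerSpec, n_min: int | None = None, n_max: int = 100):
    """(n, power) table across a range of subject counts, for reporting."""
    if n_min is None:
        n_min = spec.k + 1
    return [(n, icc_power(n, spec)) for n in range(n_min, n_max + 1)]
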