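"""Power and sample size for two-group log2 fold-change detection.

The detectability of a fold change ``FC`` with per-group size ``n`` and
log2-scale noise sd ``sigma`` under the pooled two-sample t-test follows
the noncentral t distribution with ``df = 2n - 2`` and noncentrality

    delta = log2(FC) / sigma * sqrt(n / 2).

Analytic power (``power_t_test``), the minimal per-group ``n`` reaching a
target power (``required_n``), and a seeded Monte-Carlo estimate
(``mc_power``) that serves as an independent check are provided. Default
is a two-sided test.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .containers import ParameterError

__all__ = ["PowerSpec", "power_t_test", "required_n", "mc_power"]


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power specification (log2-scale sd, fold ratio)."""

    n_per_group: int
    sd: float
    fold_change: float
    alpha: float = 0.01
    tails: str = "two"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not (math.isfinite(self.sd) and self.sd > 0):
            raise ParameterError("sd must be finite and > 0")
        if not (math.isfinite(self.fold_change) and self.fold_change > 0):
            raise ParameterError("fold_change must be a positive ratio")
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError("alpha must be in (0, 1]")
        if self.tails not in ("one", "two"):
            raise ParameterError("tails must be 'one' or 'two'")

    @property
    def noncentrality(self) -> float:
        return (abs(math.log2(self.fold_change)) / self.sd
                * math.sqrt(self.n_per_group / 2.0))


def power_t_test(spec: PowerSpec) -> float:
    """Exact power of the pooled two-sample t-test via the noncentral t."""
    df = 2 * spec.n_per_group - 2
    nc = spec.noncentrality
    if spec.alpha == 1.0:
        return 1.0
    if spec.tails == "two":
        t_crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        upper = stats.nct.sf(t_crit, df, nc)
        # the opposite tail underflows (NaN) at large noncentrality
        lower = stats.nct.cdf(-t_crit, df, nc)
        power = upper + (lower if math.isfinite(lower) else 0.0)
    else:
        t_crit = stats.t.ppf(1.0 - spec.alpha, df)
        power = stats.nct.sf(t_crit, df, nc)
    if not math.isfinite(power):
        # far-tail fallback: normal approximation of the noncentral t
        power = stats.norm.sf(t_crit - nc)
    return float(min(1.0, max(0.0, power)))


def required_n(sd: float, fold_change: float, alpha: float,
               target_power: float, tails: str = "two",
               max_n: int = 10_000) -> int:
    """Smallest per-group n whose analytic power reaches ``target_power``."""
    if not alpha < target_power < 1.0:
        raise ParameterError("target_power must lie in (alpha, 1)")
    for n in range(2, max_n + 1):
        spec = PowerSpec(n, sd, fold_change, alpha, tails)
        if power_t_test(spec) >= target_power:
            return n
    raise ParameterError(f"target power unreachable within n <= {max_n}")


def mc_power(spec: PowerSpec, n_sim: int = 200_000,
             seed: int | None = None) -> tuple[float, float]:
    """Monte-Carlo power estimate and its binomial standard error.

    Simulates ``n_sim`` experiments with the planted log2 difference, runs
    the pooled t-test on each, and reports the rejection fraction.
    """
    if n_sim < 1000:
        raise ParameterError("n_sim must be >= 1000")
    if seed is None:
        raise ParameterError("an integer seed is required")
    rng = np.random.default_rng(seed)
    n = spec.n_per_group
    d = abs(math.log2(spec.fold_change))
    xa = rng.normal(d, spec.sd, (n_sim, n))
    xb = rng.normal(0.0, spec.sd, (n_sim, n))
    m1, m2 = xa.mean(axis=1), xb.mean(axis=1)
    sp2 = (xa.var(axis=1, ddof=1) + xb.var(axis=1, ddof=1)) / 2.0
    se = np.sqrt(sp2 * 2.0 / n)
    t = (m1 - m2) / se
    df = 2 * n - 2
    if spec.tails == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    power = float((p <= spec.alpha).mean())
    se_hat = math.sqrt(power * (1.0 - power) / n_sim)
    return power, se_hat
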