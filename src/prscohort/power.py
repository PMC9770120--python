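"""Analytic and simulation power for an unmatched case-control allelic test.

The log-additive (per-allele) model: with control effect-allele frequency
p0 and per-allele odds ratio OR, the case frequency is
``p1 = p0*OR / (1 + p0*(OR - 1))``. The allelic test compares the two
frequencies over 2*n alleles per group with a two-proportion z statistic,
so power at a two-sided level alpha is

    z = |p1 - p0| / sqrt(p1(1-p1)/(2 n_cases) + p0(1-p0)/(2 n_controls))
    power = Phi(z - z_{1-alpha/2})

A Monte-Carlo cross-check simulates allele-count tables under the same
model and applies the same test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["PowerSpec", "cc_power", "cc_power_sim", "case_allele_freq"]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a case-control per-allele power calculation."""

    or_per_allele: float
    maf: float  # control effect-allele frequency
    n_cases: int
    n_controls: int
    alpha: float = 0.05  # two-sided significance level

    def __post_init__(self) -> None:
        if self.or_per_allele <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie strictly in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")


def case_allele_freq(p0: float, odds_ratio: float) -> float:
    """Case effect-allele frequency implied by a per-allele odds ratio."""
    return p0 * odds_ratio / (1.0 + p0 * (odds_ratio - 1.0))


def cc_power(spec: PowerSpec) -> float:
    """Analytic power of the two-sided allelic case-control test."""
    p0 = spec.maf
    p1 = case_allele_freq(p0, spec.or_per_allele)
    se = np.sqrt(
        p1 * (1 - p1) / (2 * spec.n_cases) + p0 * (1 - p0) / (2 * spec.n_controls)
    )
    z = abs(p1 - p0) / se
    z_crit = norm.ppf(1 - spec.alpha / 2)
    # both rejection tails; the wrong-direction tail only matters near OR=1
    return float(norm.cdf(z - z_crit) + norm.cdf(-z - z_crit))


def cc_power_sim(
    spec: PowerSpec, n_reps: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo power with a 95% binomial CI.

    Simulates case/control allele counts as binomials over 2n alleles and
    applies the pooled two-proportion z test per replicate.
    """
    if n_reps < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(seed)
    p0 = spec.maf
    p1 = case_allele_freq(p0, spec.or_per_allele)
    m_ca, m_co = 2 * spec.n_cases, 2 * spec.n_controls
    x1 = rng.binomial(m_ca, p1, size=n_reps)
    x0 = rng.binomial(m_co, p0, size=n_reps)
    f1, f0 = x1 / m_ca, x0 / m_co
    pooled = (x1 + x0) / (m_ca + m_co)
    se = np.sqrt(pooled * (1 - pooled) * (1 / m_ca + 1 / m_co))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (f1 - f0) / se, 0.0)
    reject = np.abs(z) > norm.ppf(1 - spec.alpha / 2)
    power = float(reject.mean())
    half = 1.959964 * np.sqrt(power * (1 - power) / n_reps)
    return power, (max(0.0, power - half), min(1.0, power + half))
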