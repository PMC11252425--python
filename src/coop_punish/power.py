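"""Noncentral chi-square power and sensitivity computations.

Sensitivity of a chi-square-family test (such as the 1-df ΔG² equality
tests) is expressed as the minimal detectable Cohen's w: the effect size
at which the test reaches a requested power.  Power is governed by the
noncentral chi-square distribution with noncentrality λ = w² · N_total,
where N_total is the number of multinomial observations (game trials).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize
from scipy.stats import chi2, ncx2

__all__ = [
    "PowerQuery",
    "SensitivityResult",
    "chisq_p",
    "solve_noncentrality",
    "sensitivity_w",
    "power_at",
]

_LAMBDA_LO = 1e-8
_LAMBDA_HI = 1e6


@dataclass(frozen=True)
class PowerQuery:
    alpha: float
    power: float
    df: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


@dataclass(frozen=True)
class SensitivityResult:
    noncentrality: float
    w: float


def chisq_p(stat: float, df: int) -> float:
    """Upper-tail probability of the central chi-square distribution."""
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    if stat < 0:
        raise ValueError("statistic must be non-negative")
    return float(chi2.sf(stat, df))


def solve_noncentrality(alpha: float, power: float, df: int) -> float:
    """Noncentrality λ at which the test attains the requested power.

    Solves ``P(X > crit) = power`` for a noncentral chi-square variable
    X with ``df`` degrees of freedom, where ``crit`` is the central
    α-critical value.  At λ=0 the exceedance probability equals α, so a
    requested power of α returns (numerically) zero.
    """
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    crit = chi2.ppf(1 - alpha, df)

    def gap(lam: float) -> float:
        return ncx2.sf(crit, df, lam) - power

    if gap(_LAMBDA_LO) >= 0:
        return 0.0
    if gap(_LAMBDA_HI) < 0:
        raise ValueError(f"no solution with noncentrality below {_LAMBDA_HI:g}")
    return float(optimize.brentq(gap, _LAMBDA_LO, _LAMBDA_HI, rtol=1e-12))


def sensitivity_w(query: PowerQuery) -> SensitivityResult:
    """Minimal detectable effect size w for the given design.

    w = sqrt(λ / N_total) with λ from :func:`solve_noncentrality`.
    """
    lam = solve_noncentrality(query.alpha, query.power, query.df)
    return SensitivityResult(noncentrality=lam, w=math.sqrt(lam / query.n_total))


def power_at(w: float, alpha: float, df: int, n_total: int) -> float:
    """Achieved power of the test at effect size ``w``.

    Noncentral upper-tail probability at λ = w²·N_total beyond the
    central critical value.  At w=0 this equals α.
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1 or n_total < 1:
        raise ValueError("df and n_total must be >= 1")
    crit = chi2.ppf(1 - alpha, df)
    lam = w * w * n_total
    if lam == 0:
        return float(alpha)
    return float(ncx2.sf(crit, df, lam))
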