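"""Heterogeneity statistics: Q, I-squared, and the zeta-squared parameter.

zeta-squared is the precision-weighted average squared deviation of the study
effects from the precision-weighted average effect.  Unlike the
random-effects variance tau-squared it is defined on the studies at hand, not
on a hypothetical population of studies.  Under normal effect estimates the Q
statistic is noncentral chi-square with k-1 degrees of freedom and
noncentrality ``lambda = Phi * zeta2``, which yields both a moment estimator
and an inverted-probability confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import MetaInput, pooled_estimate

__all__ = [
    "HeterogeneityResult",
    "q_statistic",
    "i_squared",
    "zeta2_moment",
    "zeta2_deviation",
    "zeta2_pairwise",
    "zeta2_ci_noncentral",
    "heterogeneity_summary",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Q, I-squared and the zeta-squared estimate with optional interval.

    ``zeta2_raw`` is the untruncated moment estimate ``(Q - df) / Phi`` and
    may be negative; ``zeta2`` is its truncation at zero.
    """

    Q: float
    df: int
    I2: float
    zeta2_raw: float
    zeta2: float
    Phi: float
    ci: tuple[float, float] | None = None
    level: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be nonnegative")
        if not 0 <= self.I2 <= 1:
            raise ValueError("I2 must lie in [0, 1]")
        if abs(self.zeta2 - max(0.0, self.zeta2_raw)) > 1e-12:
            raise ValueError("zeta2 must be the truncation of zeta2_raw at 0")
        if self.ci is not None and self.ci[0] < 0:
            raise ValueError("zeta2 interval endpoints must be nonnegative")


def q_statistic(input: MetaInput) -> tuple[float, int]:
    """Cochran's Q against the pooled estimate, with its degrees of freedom.

    ``Q = sum(se_i**-2 (beta_i - beta_F)**2)``; df = k - 1.
    """
    center = pooled_estimate(input).estimate
    q = float(np.sum(input.se**-2.0 * (input.estimate - center) ** 2))
    return q, input.k - 1


def i_squared(Q: float, df: int) -> float:
    """Proportion of total variation attributed to heterogeneity.

    ``max(0, (Q - df) / Q)``, conventionally truncated at zero; defined as 0
    when Q = 0.
    """
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q)


def zeta2_moment(Q: float, df: int, Phi: float) -> tuple[float, float]:
    """Moment estimate of zeta-squared, raw and truncated.

    Returns ``((Q - df) / Phi, max(0, (Q - df) / Phi))``.  Under homogeneity
    E[Q] = df, so the raw estimator is unbiased for zeta-squared before
    truncation.
    """
    if Phi <= 0:
        raise ValueError("Phi must be positive")
    raw = (Q - df) / Phi
    return raw, max(0.0, raw)


def zeta2_deviation(betas: Sequence[float], weights: Sequence[float]) -> float:
    """Deviation form: weighted mean squared deviation from the weighted mean."""
    betas = np.asarray(betas, dtype=float)
    w = np.asarray(weights, dtype=float)
    center = w @ betas / w.sum()
    return float(w @ (betas - center) ** 2 / w.sum())


def zeta2_pairwise(input: MetaInput, true_betas: Sequence[float]) -> float:
    """Pairwise form of zeta-squared on given effect values.

    ``sum_{i<j} w_i w_j (beta_i - beta_j)**2 / (sum w)**2`` with precision
    weights ``w_i = se_i**-2`` taken from the input.  Algebraically identical
    to the deviation form on the same betas and weights.
    """
    betas = np.asarray(true_betas, dtype=float)
    if betas.size != input.k:
        raise ValueError("true_betas must have one entry per study")
    w = input.se**-2.0
    diff2 = (betas[:, None] - betas[None, :]) ** 2
    total = 0.5 * float(w @ diff2 @ w)
    return total / float(w.sum()) ** 2


def zeta2_ci_noncentral(
    Q: float, df: int, Phi: float, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for zeta-squared by noncentral chi-square inversion.

    The interval is the set of zeta2 whose noncentrality ``lambda = Phi*zeta2``
    keeps Q between the alpha/2 and 1-alpha/2 quantiles of
    ``ncx2(df, lambda)``.  The lower endpoint solves
    ``P(ncx2(df, lam) <= Q) = 1 - alpha/2`` (zero if Q is below the central
    1-alpha/2 quantile); the upper endpoint solves
    ``P(ncx2(df, lam) <= Q) = alpha/2`` (zero if Q is below the central
    alpha/2 quantile).  Roots are bracketed and refined to 1e-8 on lambda.
    """
    if Q < 0 or Phi <= 0:
        raise ValueError("require Q >= 0 and Phi > 0")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lam_lo = _invert_ncx2_cdf(Q, df, target=1.0 - alpha / 2.0)
    lam_hi = _invert_ncx2_cdf(Q, df, target=alpha / 2.0)
    return (lam_lo / Phi, lam_hi / Phi)


def _invert_ncx2_cdf(Q: float, df: int, target: float) -> float:
    """Solve P(ncx2(df, lam) <= Q) = target for lam >= 0 (0 if unattainable).

    The cdf at fixed Q is strictly decreasing in lam, so a sign change is
    found by doubling the upper bracket.
    """
    if stats.chi2.cdf(Q, df) <= target:
        return 0.0

    def g(lam: float) -> float:
        return stats.ncx2.cdf(Q, df, lam) - target

    hi = max(Q, 1.0)
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"noncentrality bracket did not close: cdf({Q}, {df}, {hi}) still "
            f"above {target}"
        )
    return float(optimize.brentq(g, 0.0, hi, xtol=1e-8))


def heterogeneity_summary(
    input: MetaInput, level: float = 0.95, with_ci: bool = True
) -> HeterogeneityResult:
    """Full heterogeneity summary with the noncentral chi-square interval."""
    q, df = q_statistic(input)
    raw, trunc = zeta2_moment(q, df, input.Phi)
    ci = zeta2_ci_noncentral(q, df, input.Phi, level) if with_ci else None
    return HeterogeneityResult(
        Q=q,
        df=df,
        I2=i_squared(q, df),
        zeta2_raw=raw,
        zeta2=trunc,
        Phi=input.Phi,
        ci=ci,
        level=level if with_ci else None,
        method="noncentral_chi2" if with_ci else None,
    )
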