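"""Quasi-F test and interval for the precision-weighted average effect.

Under normal effect estimates Q is noncentral chi-square(k-1, Phi*zeta2) and
independent of the pooled estimate.  Matching the first two moments of that
noncentral law to a scaled central chi-square (Patnaik's approximation) gives
a scale ``1 + lam/((k-1)+lam)`` and degrees of freedom
``(k-1) + lam**2/((k-1)+2*lam)``; the ratio of the squared standardized
pooled estimate to ``Q/(scale*df)`` is then approximately F(1, df), and its
signed square root approximately Student t with (non-integer) df.  Inverting
the t test yields a confidence interval that widens appropriately for few
studies and small information-times-heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import copysign, sqrt

import numpy as np
from scipy import stats

from .core import LocationResult, MetaInput, pooled_estimate
from .heterogeneity import q_statistic, zeta2_moment
from .inflation import inflation_factor

__all__ = ["PatnaikParams", "patnaik_params", "quasi_f_test", "quasi_f_interval"]


@dataclass(frozen=True)
class PatnaikParams:
    """Scale and degrees of freedom of the moment-matched central chi-square.

    Satisfies ``scale*df = (k-1) + lam`` and ``2*scale**2*df = 2(k-1) + 4*lam``
    (mean and variance of the noncentral chi-square being matched).
    """

    scale: float
    df: float
    lambda_hat: float

    def __post_init__(self) -> None:
        if self.scale < 1 or self.df <= 0 or self.lambda_hat < 0:
            raise ValueError("require scale >= 1, df > 0, lambda_hat >= 0")


def patnaik_params(lam: float, k: int) -> PatnaikParams:
    """Moment-match ncx2(k-1, lam) to ``scale * chi2(df)``."""
    if lam < 0:
        raise ValueError("noncentrality lambda must be nonnegative")
    if k < 2:
        raise ValueError("k must be >= 2")
    m = k - 1
    scale = 1.0 + lam / (m + lam)
    df = m + lam**2 / (m + 2.0 * lam) if lam > 0 else float(m)
    return PatnaikParams(scale=scale, df=df, lambda_hat=lam)


def _quasi_f_pieces(input: MetaInput) -> tuple[float, float, float, PatnaikParams]:
    """(pooled estimate, LSSA variance, Q, Patnaik params) shared by test/CI."""
    pooled = pooled_estimate(input)
    lssa_var = inflation_factor(input, center=pooled.estimate).lssa_variance
    q, df = q_statistic(input)
    if q <= 0:
        raise ValueError(
            "quasi-F statistic undefined: Q = 0 (input homogeneous to machine "
            "precision)"
        )
    _, zeta2_trunc = zeta2_moment(q, df, input.Phi)
    params = patnaik_params(input.Phi * zeta2_trunc, input.k)
    return pooled.estimate, lssa_var, q, params


def quasi_f_test(input: MetaInput, beta0: float = 0.0) -> tuple[float, float, float]:
    """Signed-root quasi-F test of H0: beta_F = beta0.

    Returns ``(t, ref_df, p)`` where
    ``t = sign(est - beta0) * sqrt(scale*df*(est-beta0)**2 / (lssa_var * Q))``
    is referred to a Student t with the Patnaik degrees of freedom.
    """
    est, lssa_var, q, params = _quasi_f_pieces(input)
    t2 = params.scale * params.df * (est - beta0) ** 2 / (lssa_var * q)
    t = copysign(sqrt(t2), est - beta0)
    p = 2.0 * stats.t.sf(abs(t), params.df)
    return t, params.df, float(p)


def quasi_f_interval(input: MetaInput, level: float = 0.95) -> LocationResult:
    """Interval for beta_F from inverting the quasi-F test.

    ``est +/- t_{df,1-a/2} * sqrt(lssa_var * Q / (scale*df))``; feeding either
    endpoint back through :func:`quasi_f_test` returns two-sided p = 1-level.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    est, lssa_var, q, params = _quasi_f_pieces(input)
    tq = stats.t.ppf(0.5 + level / 2.0, params.df)
    half = tq * sqrt(lssa_var * q / (params.scale * params.df))
    return LocationResult(
        estimate=est,
        se=sqrt(lssa_var * q / (params.scale * params.df)),
        ci=(est - half, est + half),
        level=level,
        method="quasi_f",
        ref_df=params.df,
    )
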