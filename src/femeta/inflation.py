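"""Variance inflation from estimated standard errors, and the LSSA interval.

Plugging estimated precisions into the precision-weighted average inflates
its variance by a factor that does not vanish in large samples: the naive
variance ``1/Phi`` is multiplied by
``1 + sum(n_i (beta_i - beta_F)**2 f_i) / sum(n_i phi_i)``, where
``phi_i`` is the per-subject Fisher information on the effect and ``f_i`` is
the asymptotic variance of ``sqrt(n_i)(phi_hat_i - phi_i)``.  The factor is 1
under homogeneity and grows with the heterogeneity zeta-squared.  The
large-sample-size-approximation (LSSA) interval is the normal-quantile
interval built on the inflated variance; the analytic coverage of the naive
interval follows from the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LocationResult, MetaInput, StudySummary, pooled_estimate

__all__ = [
    "InfoModel",
    "InflationResult",
    "info_model",
    "inflation_factor",
    "lssa_interval",
    "naive_asymptotic_coverage",
]


@dataclass(frozen=True)
class InfoModel:
    """Per-subject information and the variance of its estimate.

    ``phi_hat = 1/(n * s**2)`` estimates the per-subject Fisher information;
    ``f_hat`` is the asymptotic variance of ``sqrt(n)(phi_hat - phi)`` under
    the study's variance model (0 when the standard error is known).
    """

    phi_hat: float
    f_hat: float
    model: str

    def __post_init__(self) -> None:
        if self.phi_hat <= 0:
            raise ValueError("phi_hat must be positive")
        if self.f_hat < 0:
            raise ValueError("f_hat must be nonnegative")
        if (self.f_hat == 0) != (self.model == "known"):
            raise ValueError("f_hat is 0 exactly when the model is 'known'")


@dataclass(frozen=True)
class InflationResult:
    """Inflation factor, its per-study contributions, and the LSSA variance."""

    factor: float
    per_study_terms: np.ndarray
    lssa_variance: float

    def __post_init__(self) -> None:
        if self.factor < 1.0 - 1e-12:
            raise ValueError("inflation factor must be >= 1")


def info_model(study: StudySummary, f_override: float | None = None) -> InfoModel:
    """Information model for one study.

    For chi-square-distributed residual variances (``pooled_normal`` and
    ``linear_regression``) the precision estimate is inverse-chi-square and
    the exact delta-method variance gives ``f_hat = 2 phi_hat**2 (n/df)``,
    which tends to ``2 phi_hat**2`` for large n.  For ``welch_normal`` the two
    arm variances are resampled separately; each arm contributes
    ``n (dphi/dvar_j)**2 * 2 var_j**2 / (n_j - 1)``, which collapses to the
    pooled formula when arms and variances are equal.  ``f_override`` replaces
    the model-based value (e.g. to inject kurtosis corrections for non-normal
    outcomes).
    """
    phi_hat = 1.0 / (study.n * study.se**2)
    if f_override is not None:
        if f_override < 0:
            raise ValueError("f_override must be nonnegative")
        return InfoModel(phi_hat=phi_hat, f_hat=f_override, model=study.variance_model)
    model = study.variance_model
    if model == "known":
        f_hat = 0.0
    elif model in ("pooled_normal", "linear_regression"):
        f_hat = 2.0 * phi_hat**2 * (study.n / study.df_resid)
    elif model == "welch_normal":
        n1, n2 = study.group_n
        v1, v2 = study.group_var
        n = study.n
        # phi = 1 / (n (v1/n1 + v2/n2)); dphi/dv_j = -n phi^2 / n_j
        v = v1 / n1 + v2 / n2
        phi = 1.0 / (n * v)
        d1 = -n * phi**2 / n1
        d2 = -n * phi**2 / n2
        f_hat = n * (d1**2 * 2.0 * v1**2 / (n1 - 1) + d2**2 * 2.0 * v2**2 / (n2 - 1))
    else:  # pragma: no cover - guarded by StudySummary validation
        raise ValueError(f"unsupported variance model {model!r}")
    return InfoModel(phi_hat=phi_hat, f_hat=f_hat, model=model)


def inflation_factor(
    input: MetaInput,
    center: float | None = None,
    f_override: np.ndarray | None = None,
) -> InflationResult:
    """Variance-inflation factor of the plug-in pooled estimate.

    ``factor = 1 + sum(n_i (beta_i - center)**2 f_hat_i) / sum(n_i phi_hat_i)``
    evaluated at the plug-in pooled estimate when ``center`` is omitted.
    Note ``sum(n_i phi_hat_i) = sum(s_i**-2) = Phi``, so
    ``lssa_variance = factor / Phi``.
    """
    if center is None:
        center = pooled_estimate(input).estimate
    overrides = (
        [None] * input.k if f_override is None else list(np.asarray(f_override))
    )
    models = [info_model(s, o) for s, o in zip(input.studies, overrides)]
    n = input.n.astype(float)
    f = np.array([m.f_hat for m in models])
    phi = np.array([m.phi_hat for m in models])
    terms = n * (input.estimate - center) ** 2 * f
    denom = float(n @ phi)
    factor = 1.0 + float(terms.sum()) / denom
    return InflationResult(
        factor=factor, per_study_terms=terms, lssa_variance=factor / denom
    )


def lssa_interval(input: MetaInput, level: float = 0.95) -> LocationResult:
    """Normal-quantile interval on the inflation-corrected (LSSA) variance."""
    pooled = pooled_estimate(input, level=level)
    infl = inflation_factor(input, center=pooled.estimate)
    se = float(np.sqrt(infl.lssa_variance))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return LocationResult(
        estimate=pooled.estimate,
        se=se,
        ci=(pooled.estimate - z * se, pooled.estimate + z * se),
        level=level,
        method="lssa",
    )


def naive_asymptotic_coverage(factor: float, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic coverage of the naive interval given the inflation factor.

    The naive z-interval with halfwidth ``z_{1-a/2}/sqrt(Phi)`` covers with
    probability ``P(|Z| <= z_{1-a/2}/sqrt(factor))`` when the true sampling
    standard deviation is ``sqrt(factor/Phi)``.  Returns (coverage,
    type-I error); coverage equals the nominal level at factor 1 and
    decreases monotonically in the factor.
    """
    if factor < 1:
        raise ValueError("inflation factor must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    coverage = float(2.0 * stats.norm.cdf(z / np.sqrt(factor)) - 1.0)
    return coverage, 1.0 - coverage
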