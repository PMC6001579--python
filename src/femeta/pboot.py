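"""Parametric bootstrap for the pooled effect and zeta-squared.

Replicate effect estimates are drawn from ``N(beta_i, s_i**2)`` and replicate
variances from the scaled chi-square law implied by each study's variance
model (held fixed for ``known``; per-arm chi-square draws recombined for
``welch_normal``).  From each replicate the pooled estimate, the untruncated
zeta-squared moment estimate, and two studentized statistics (naive and
LSSA-standardized) are computed, supporting four interval constructions for
the location parameter and two for zeta-squared.

All draws come from one ``numpy.random.Generator`` (PCG64) stream seeded
explicitly: the effect matrix is filled replicate-major in a single call,
then replicate variances are drawn study-by-study, so results are exactly
reproducible given (input, B, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import LocationResult, MetaInput, pooled_estimate
from .inflation import lssa_interval

__all__ = [
    "BootstrapDraws",
    "ZetaIntervalResult",
    "draw_bootstrap",
    "boot_beta_interval",
    "boot_zeta_interval",
    "empirical_quantile",
    "BETA_BOOT_METHODS",
    "ZETA_BOOT_METHODS",
]

BETA_BOOT_METHODS = ("boot_normal", "boot_percentile", "boot_t_naive", "boot_t_lssa")
ZETA_BOOT_METHODS = ("boot_normal", "boot_percentile")


@dataclass(frozen=True)
class BootstrapDraws:
    """Seeded parametric-bootstrap replicates.

    ``beta_star`` holds replicate pooled estimates, ``zeta2_star`` the
    untruncated replicate moment estimates of zeta-squared (truncation is
    applied only to reported interval endpoints), ``t_naive_star`` and
    ``t_lssa_star`` the centered studentized replicates
    ``(beta_star - beta_hat_F) / se*`` with the replicate naive and LSSA
    standard errors respectively.
    """

    B: int
    seed: int
    beta_star: np.ndarray
    zeta2_star: np.ndarray
    t_naive_star: np.ndarray
    t_lssa_star: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beta_star", "zeta2_star", "t_naive_star", "t_lssa_star"):
            if len(getattr(self, name)) != self.B:
                raise ValueError(f"{name} must have length B = {self.B}")


@dataclass(frozen=True)
class ZetaIntervalResult:
    """Bootstrap interval for zeta-squared (endpoints truncated at 0)."""

    zeta2: float
    ci: tuple[float, float]
    level: float
    method: str


def empirical_quantile(x: np.ndarray, p: float) -> float:
    """Type-1 (inverse empirical cdf) quantile: the ceil(p*B)-th order statistic."""
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    xs = np.sort(np.asarray(x, dtype=float))
    idx = min(max(int(np.ceil(p * xs.size)), 1), xs.size)
    return float(xs[idx - 1])


def draw_bootstrap(input: MetaInput, B: int, seed: int) -> BootstrapDraws:
    """Draw B parametric-bootstrap replicates of the meta-analysis.

    Effects resample as ``N(beta_i, s_i**2)``; variances as
    ``s_i**2 * chi2(df_i)/df_i`` for ``pooled_normal`` and
    ``linear_regression``, per-arm ``chi2(n_j - 1)`` draws recombined for
    ``welch_normal``, and held fixed for ``known``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    for s in input.studies:
        if s.variance_model != "known" and s.df_resid is None:  # pragma: no cover
            raise ValueError(f"study {s.study_id!r}: df_resid required")
    rng = np.random.default_rng(seed)
    k = input.k
    beta_hat = input.estimate
    s2 = input.se**2
    n = input.n.astype(float)

    eff = rng.normal(loc=beta_hat, scale=input.se, size=(B, k))
    var = np.empty((B, k))
    # per-arm variance draws kept for the welch LSSA recomputation
    arm_draws: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, study in enumerate(input.studies):
        if study.variance_model == "known":
            var[:, i] = s2[i]
        elif study.variance_model in ("pooled_normal", "linear_regression"):
            df = study.df_resid
            var[:, i] = s2[i] * rng.chisquare(df, size=B) / df
        else:  # welch_normal
            n1, n2 = study.group_n
            v1, v2 = study.group_var
            v1s = v1 * rng.chisquare(n1 - 1, size=B) / (n1 - 1)
            v2s = v2 * rng.chisquare(n2 - 1, size=B) / (n2 - 1)
            arm_draws[i] = (v1s, v2s)
            var[:, i] = v1s / n1 + v2s / n2

    w = 1.0 / var
    phi_star = w.sum(axis=1)
    beta_f_star = (w * eff).sum(axis=1) / phi_star
    q_star = (w * (eff - beta_f_star[:, None]) ** 2).sum(axis=1)
    zeta2_star = (q_star - (k - 1)) / phi_star

    # replicate LSSA variance: factor*/Phi* with replicate info models
    f_star = np.zeros((B, k))
    for i, study in enumerate(input.studies):
        phi_i = 1.0 / (n[i] * var[:, i])
        if study.variance_model == "known":
            continue
        if study.variance_model in ("pooled_normal", "linear_regression"):
            f_star[:, i] = 2.0 * phi_i**2 * (n[i] / study.df_resid)
        else:
            n1, n2 = study.group_n
            v1s, v2s = arm_draws[i]
            d1 = -n[i] * phi_i**2 / n1
            d2 = -n[i] * phi_i**2 / n2
            f_star[:, i] = n[i] * (
                d1**2 * 2.0 * v1s**2 / (n1 - 1) + d2**2 * 2.0 * v2s**2 / (n2 - 1)
            )
    num = (n[None, :] * (eff - beta_f_star[:, None]) ** 2 * f_star).sum(axis=1)
    factor_star = 1.0 + num / phi_star
    lssa_var_star = factor_star / phi_star

    beta_hat_f = pooled_estimate(input).estimate
    t_naive = (beta_f_star - beta_hat_f) * np.sqrt(phi_star)
    t_lssa = (beta_f_star - beta_hat_f) / np.sqrt(lssa_var_star)
    return BootstrapDraws(
        B=B,
        seed=seed,
        beta_star=beta_f_star,
        zeta2_star=zeta2_star,
        t_naive_star=t_naive,
        t_lssa_star=t_lssa,
    )


def boot_beta_interval(
    draws: BootstrapDraws,
    input: MetaInput,
    level: float = 0.95,
    method: str = "boot_percentile",
) -> LocationResult:
    """Bootstrap interval for the pooled effect.

    ``boot_normal``: normal-quantile interval with the bootstrap standard
    deviation; ``boot_percentile``: empirical quantiles of the replicate
    pooled estimates; ``boot_t_naive`` / ``boot_t_lssa``: bootstrap-t with
    the naive / LSSA standard error of the original data and the matching
    studentized replicate quantiles.
    """
    if method not in BETA_BOOT_METHODS:
        raise ValueError(f"unknown bootstrap method {method!r}; expected one of "
                         f"{BETA_BOOT_METHODS}")
    alpha = 1.0 - level
    est = pooled_estimate(input).estimate
    sd = float(np.std(draws.beta_star, ddof=1))
    if method == "boot_normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        ci = (est - z * sd, est + z * sd)
    elif method == "boot_percentile":
        ci = (
            empirical_quantile(draws.beta_star, alpha / 2.0),
            empirical_quantile(draws.beta_star, 1.0 - alpha / 2.0),
        )
    elif method == "boot_t_naive":
        se = float(1.0 / np.sqrt(input.Phi))
        ci = (
            est - empirical_quantile(draws.t_naive_star, 1.0 - alpha / 2.0) * se,
            est - empirical_quantile(draws.t_naive_star, alpha / 2.0) * se,
        )
    else:  # boot_t_lssa
        se = lssa_interval(input, level).se
        ci = (
            est - empirical_quantile(draws.t_lssa_star, 1.0 - alpha / 2.0) * se,
            est - empirical_quantile(draws.t_lssa_star, alpha / 2.0) * se,
        )
    return LocationResult(estimate=est, se=sd, ci=ci, level=level, method=method)


def boot_zeta_interval(
    draws: BootstrapDraws,
    zeta2_hat: float,
    level: float = 0.95,
    method: str = "boot_percentile",
) -> ZetaIntervalResult:
    """Bootstrap interval for zeta-squared.

    ``boot_normal``: ``zeta2_hat +/- z * sd(zeta2_star)``; ``boot_percentile``:
    empirical quantiles of the untruncated replicates.  Reported endpoints are
    truncated at zero.
    """
    if method not in ZETA_BOOT_METHODS:
        raise ValueError(f"unknown bootstrap method {method!r}; expected one of "
                         f"{ZETA_BOOT_METHODS}")
    alpha = 1.0 - level
    if method == "boot_normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        sd = float(np.std(draws.zeta2_star, ddof=1))
        lo, hi = zeta2_hat - z * sd, zeta2_hat + z * sd
    else:
        lo = empirical_quantile(draws.zeta2_star, alpha / 2.0)
        hi = empirical_quantile(draws.zeta2_star, 1.0 - alpha / 2.0)
    return ZetaIntervalResult(
        zeta2=zeta2_hat,
        ci=(max(0.0, lo), max(0.0, hi)),
        level=level,
        method=method,
    )
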