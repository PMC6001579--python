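"""Monte-Carlo harness for coverage properties of the interval methods.

A :class:`Scenario` fixes the study conditions: k studies of balanced two-arm
normal outcomes with n subjects each, within-subject variance ``sigma2_within``,
and true mean-difference effects uniformly spaced around ``beta_F_true`` with
precision-weighted mean squared deviation ``zeta2_true``.  Each replicate
draws effect estimates from their normal sampling law and variance estimates
from scaled chi-square laws with n-2 degrees of freedom, runs the requested
interval constructions, and records whether each interval covers the
generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MetaInput, StudySummary, dersimonian_laird, pooled_estimate
from .heterogeneity import q_statistic, zeta2_ci_noncentral, zeta2_moment
from .inflation import lssa_interval
from .pboot import boot_beta_interval, boot_zeta_interval, draw_bootstrap
from .quasif import quasi_f_interval

__all__ = [
    "Scenario",
    "make_scenario",
    "simulate_summaries",
    "coverage_experiment",
    "BETA_METHODS",
    "ZETA_METHODS",
]

#: Interval constructions for the location parameter beta_F.
BETA_METHODS = (
    "naive",
    "lssa",
    "quasi_f",
    "boot_normal",
    "boot_percentile",
    "boot_t_naive",
    "boot_t_lssa",
    "dersimonian_laird",
)
#: Interval constructions for zeta-squared (namespaced to keep one flat list).
ZETA_METHODS = ("noncentral_chi2", "zeta2_boot_normal", "zeta2_boot_percentile")

_BOOT_METHODS = frozenset(
    {"boot_normal", "boot_percentile", "boot_t_naive", "boot_t_lssa",
     "zeta2_boot_normal", "zeta2_boot_percentile"}
)


@dataclass(frozen=True)
class Scenario:
    """Fixed-effects simulation scenario (balanced two-arm normal outcomes)."""

    k: int
    n: int
    zeta2_true: float
    beta_F_true: float
    sigma2_within: float
    true_betas: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        b = np.asarray(self.true_betas, dtype=float)
        object.__setattr__(self, "true_betas", b)
        if abs(b.mean() - self.beta_F_true) > 1e-10:
            raise ValueError("true_betas must center on beta_F_true")
        if abs(np.mean((b - b.mean()) ** 2) - self.zeta2_true) > 1e-10:
            raise ValueError("true_betas must have mean squared deviation zeta2_true")

    @property
    def sigma2(self) -> float:
        """True sampling variance of each mean-difference estimate, 4*sigma2/n."""
        return 4.0 * self.sigma2_within / self.n


def make_scenario(
    k: int,
    n: int,
    zeta2_true: float,
    beta_F_true: float = 0.0,
    sigma2_within: float = 1.0,
    seed: int = 0,
) -> Scenario:
    """Uniformly spaced true effects with the requested heterogeneity.

    The grid ``beta_i = beta_F_true + d*(i - (k+1)/2)`` with
    ``d = sqrt(12*zeta2_true/(k**2 - 1))`` has equal-weight mean squared
    deviation exactly ``zeta2_true``; with equal per-study precision this is
    also the precision-weighted heterogeneity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 6 or n % 2:
        raise ValueError("n must be even and >= 6 (balanced two-arm design)")
    if zeta2_true < 0:
        raise ValueError("zeta2_true must be nonnegative")
    if sigma2_within <= 0:
        raise ValueError("sigma2_within must be positive")
    idx = np.arange(1, k + 1, dtype=float)
    if zeta2_true > 0:
        d = np.sqrt(12.0 * zeta2_true / (k**2 - 1.0))
        betas = beta_F_true + d * (idx - (k + 1) / 2.0)
    else:
        betas = np.full(k, beta_F_true)
    return Scenario(
        k=k,
        n=n,
        zeta2_true=zeta2_true,
        beta_F_true=beta_F_true,
        sigma2_within=sigma2_within,
        true_betas=betas,
        seed=seed,
    )


def simulate_summaries(
    scenario: Scenario,
    rng: np.random.Generator,
    known_sigma: bool = False,
) -> MetaInput:
    """One replicate of study summaries under the scenario.

    Effect estimates are ``N(beta_i, 4*sigma2_within/n)``; residual-variance
    estimates are ``sigma2_within * chi2(n-2)/(n-2)`` so the estimated
    standard errors are ``sqrt(4*s2_i/n)`` with n-2 residual df.  With
    ``known_sigma`` the true sigma is reported and the rows are tagged
    ``known`` (the calibration benchmark).
    """
    k, n = scenario.k, scenario.n
    sigma2 = scenario.sigma2
    beta_hat = rng.normal(scenario.true_betas, np.sqrt(sigma2))
    if known_sigma:
        se = np.full(k, np.sqrt(sigma2))
        model, df = "known", None
    else:
        s2_within = scenario.sigma2_within * rng.chisquare(n - 2, size=k) / (n - 2)
        se = np.sqrt(4.0 * s2_within / n)
        model, df = "pooled_normal", n - 2
    studies = tuple(
        StudySummary(
            study_id=f"study_{i + 1}",
            estimate=float(beta_hat[i]),
            se=float(se[i]),
            n=n,
            variance_model=model,
            df_resid=df,
        )
        for i in range(k)
    )
    return MetaInput(studies=studies)


def _beta_interval(method, meta, draws, level):
    if method == "naive":
        return pooled_estimate(meta, level=level).ci
    if method == "lssa":
        return lssa_interval(meta, level).ci
    if method == "quasi_f":
        return quasi_f_interval(meta, level).ci
    if method == "dersimonian_laird":
        return dersimonian_laird(meta, level).ci
    return boot_beta_interval(draws, meta, level, method).ci


def _zeta_interval(method, meta, draws, level):
    q, df = q_statistic(meta)
    _, zeta2 = zeta2_moment(q, df, meta.Phi)
    if method == "noncentral_chi2":
        return zeta2_ci_noncentral(q, df, meta.Phi, level)
    return boot_zeta_interval(
        draws, zeta2, level, method.removeprefix("zeta2_")
    ).ci


def coverage_experiment(
    scenario: Scenario,
    methods: Sequence[str],
    reps: int = 2000,
    B: int = 500,
    seed: int | None = None,
    level: float = 0.95,
    known_sigma: bool = False,
) -> pd.DataFrame:
    """Empirical coverage and width of the requested interval methods.

    Returns a tidy frame with one row per method: empirical ``coverage`` of
    the scenario truth (``beta_F_true`` for location methods,
    ``zeta2_true`` for the zeta-squared methods), ``mean_width``, ``reps``,
    and the binomial Monte-Carlo standard error
    ``sqrt(coverage*(1-coverage)/reps)``.  Fully seeded: bootstrap seeds are
    drawn from the same generator stream.
    """
    for m in methods:
        if m not in BETA_METHODS and m not in ZETA_METHODS:
            raise ValueError(
                f"unknown method {m!r}; expected one of "
                f"{BETA_METHODS + ZETA_METHODS}"
            )
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    need_boot = any(m in _BOOT_METHODS for m in methods)
    hits = {m: 0 for m in methods}
    widths = {m: 0.0 for m in methods}
    for _ in range(reps):
        meta = simulate_summaries(scenario, rng, known_sigma=known_sigma)
        draws = (
            draw_bootstrap(meta, B, seed=int(rng.integers(2**31)))
            if need_boot
            else None
        )
        for m in methods:
            if m in ZETA_METHODS:
                lo, hi = _zeta_interval(m, meta, draws, level)
                truth = scenario.zeta2_true
            else:
                lo, hi = _beta_interval(m, meta, draws, level)
                truth = scenario.beta_F_true
            hits[m] += lo <= truth <= hi
            widths[m] += hi - lo
    rows = []
    for m in methods:
        cov = hits[m] / reps
        rows.append(
            {
                "method": m,
                "target": "zeta2" if m in ZETA_METHODS else "beta_F",
                "coverage": cov,
                "mean_width": widths[m] / reps,
                "reps": reps,
                "mc_se": float(np.sqrt(cov * (1.0 - cov) / reps)),
            }
        )
    return pd.DataFrame(rows)
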