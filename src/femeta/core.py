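"""Domain types and pooled location estimators for fixed-effects meta-analysis.

The central object is :class:`MetaInput`, a validated collection of per-study
summaries (effect estimate, standard error, sample size, variance-model
metadata).  On top of it this module provides inverse-variance weighting, the
general minimum-variance affine combination for correlated estimates, the
precision-weighted pooled estimate (identical arithmetic whether the standard
errors are treated as known or as plug-in estimates), and the
DerSimonian-Laird random-effects estimator used as a comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, isfinite
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VARIANCE_MODELS",
    "StudySummary",
    "MetaInput",
    "WeightVector",
    "LocationResult",
    "RandomEffectsResult",
    "validate_input",
    "inverse_variance_weights",
    "optimal_affine_weights",
    "pooled_estimate",
    "dersimonian_laird",
]

#: Supported within-study variance models.  ``known`` means the standard error
#: is treated as exact; the others describe how the variance estimate was
#: obtained and hence how it resamples (scaled chi-square laws).
VARIANCE_MODELS = ("known", "pooled_normal", "welch_normal", "linear_regression")


@dataclass(frozen=True)
class StudySummary:
    """One study's summary statistics.

    Parameters
    ----------
    study_id : str
        Label used in error messages and reports.
    estimate : float
        The study's effect estimate (e.g. a mean difference).
    se : float
        Standard error of the estimate; an estimated ``s_i`` unless
        ``variance_model == "known"``, in which case it is the true
        ``sigma_i``.
    n : int
        Total number of subjects in the study.
    variance_model : str
        One of :data:`VARIANCE_MODELS`.
    df_resid : int, optional
        Residual degrees of freedom of the variance estimate (``n - 2`` for a
        two-arm pooled-variance design, ``n - p`` for linear regression).
        Auto-filled as ``n - 2`` for ``pooled_normal`` and ``welch_normal``
        when omitted; required for ``linear_regression``.
    group_n, group_var : pair of floats, optional
        Per-arm sample sizes and variance estimates; required for
        ``welch_normal``.
    """

    study_id: str
    estimate: float
    se: float
    n: int
    variance_model: str = "pooled_normal"
    df_resid: int | None = None
    group_n: tuple[int, int] | None = None
    group_var: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.variance_model not in VARIANCE_MODELS:
            raise ValueError(
                f"study {self.study_id!r}: unknown variance_model "
                f"{self.variance_model!r}; expected one of {VARIANCE_MODELS}"
            )
        if not (self.se > 0 and isfinite(self.se)):
            raise ValueError(
                f"study {self.study_id!r}: standard error must be positive "
                f"and finite, got {self.se!r}"
            )
        if not isfinite(self.estimate):
            raise ValueError(f"study {self.study_id!r}: non-finite estimate")
        if self.n < 1:
            raise ValueError(f"study {self.study_id!r}: n must be >= 1")
        if self.variance_model != "known":
            if self.n < 3:
                raise ValueError(
                    f"study {self.study_id!r}: n >= 3 required when the "
                    "standard error is estimated"
                )
            if self.df_resid is None:
                if self.variance_model in ("pooled_normal", "welch_normal"):
                    object.__setattr__(self, "df_resid", self.n - 2)
                else:
                    raise ValueError(
                        f"study {self.study_id!r}: df_resid required for "
                        "linear_regression variance model"
                    )
            if not (1 <= self.df_resid < self.n):
                raise ValueError(
                    f"study {self.study_id!r}: df_resid must satisfy "
                    f"1 <= df_resid < n, got {self.df_resid}"
                )
        if self.variance_model == "welch_normal":
            if self.group_n is None or self.group_var is None:
                raise ValueError(
                    f"study {self.study_id!r}: welch_normal requires group_n "
                    "and group_var"
                )
            if min(self.group_n) < 2 or min(self.group_var) <= 0:
                raise ValueError(
                    f"study {self.study_id!r}: group_n must be >= 2 and "
                    "group_var positive"
                )

    @property
    def variance(self) -> float:
        """Sampling variance of the estimate, ``se**2``."""
        return self.se**2


@dataclass(frozen=True)
class MetaInput:
    """Validated collection of study summaries with derived totals.

    Attributes
    ----------
    studies : tuple of StudySummary
    N : int
        Total subjects across studies.
    eta : ndarray
        Sample fractions ``n_i / N`` (sum to 1).
    Phi : float
        Total information, ``sum(se_i**-2)``.
    """

    studies: tuple[StudySummary, ...]
    N: int = field(init=False)
    eta: np.ndarray = field(init=False, repr=False)
    Phi: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.studies) < 2:
            raise ValueError(
                f"meta-analysis requires at least 2 studies, got {len(self.studies)}"
            )
        n = np.array([s.n for s in self.studies], dtype=float)
        object.__setattr__(self, "N", int(n.sum()))
        object.__setattr__(self, "eta", n / n.sum())
        phi = float(np.sum(self.se**-2.0))
        if not (phi > 0 and isfinite(phi)):
            raise ValueError("total information Phi must be positive and finite")
        object.__setattr__(self, "Phi", phi)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def estimate(self) -> np.ndarray:
        return np.array([s.estimate for s in self.studies])

    @property
    def se(self) -> np.ndarray:
        return np.array([s.se for s in self.studies])

    @property
    def n(self) -> np.ndarray:
        return np.array([s.n for s in self.studies])

    @property
    def df_resid(self) -> np.ndarray:
        return np.array(
            [s.df_resid if s.df_resid is not None else -1 for s in self.studies]
        )


@dataclass(frozen=True)
class WeightVector:
    """Affine weights (summing to 1) and the variance of the combination."""

    weights: np.ndarray
    variance_of_combination: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not self.variance_of_combination > 0:
            raise ValueError("variance_of_combination must be positive")


@dataclass(frozen=True)
class LocationResult:
    """Point estimate of a pooled location parameter with its interval."""

    estimate: float
    se: float
    ci: tuple[float, float]
    level: float
    method: str
    ref_df: float = inf

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must lie in (0, 1)")


@dataclass(frozen=True)
class RandomEffectsResult:
    """DerSimonian-Laird random-effects summary (mu, tau-squared)."""

    mu_hat: float
    tau2_hat: float
    se: float
    ci: tuple[float, float]
    level: float
    method: str = "dersimonian_laird"


def _as_study(row: StudySummary | Mapping, index: int) -> StudySummary:
    if isinstance(row, StudySummary):
        return row
    kwargs = dict(row)
    kwargs.setdefault("study_id", f"study_{index + 1}")
    return StudySummary(**kwargs)


def validate_input(rows: Iterable[StudySummary | Mapping]) -> MetaInput:
    """Validate study summaries and assemble a :class:`MetaInput`.

    Accepts :class:`StudySummary` objects or mappings with the same fields.
    Study order is preserved.  Raises ``ValueError`` naming the offending
    study on any invariant breach; fewer than two studies is rejected.
    """
    studies = tuple(_as_study(row, i) for i, row in enumerate(rows))
    return MetaInput(studies=studies)


def inverse_variance_weights(se: Sequence[float] | np.ndarray) -> WeightVector:
    """Precision weights ``se_i**-2 / sum(se_j**-2)``.

    The variance of the weighted combination of independent estimates with
    these standard errors is ``1 / sum(se_j**-2)``.
    """
    se = np.asarray(se, dtype=float)
    if se.size == 0:
        raise ValueError("need at least one standard error")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    prec = se**-2.0
    total = prec.sum()
    return WeightVector(weights=prec / total, variance_of_combination=1.0 / total)


def optimal_affine_weights(cov: np.ndarray) -> WeightVector:
    """Minimum-variance affine combination weights for correlated estimates.

    For an estimate vector with covariance ``cov``, the affine combination
    (weights summing to 1) of minimum variance has weights
    ``cov^-1 1 / (1' cov^-1 1)`` and variance ``(1' cov^-1 1)^-1``.  On a
    diagonal covariance this reduces to :func:`inverse_variance_weights` of
    the root diagonal.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, rtol=0, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err
    ones = np.ones(cov.shape[0])
    # solve cov x = 1 via the Cholesky factor
    x = np.linalg.solve(chol.T, np.linalg.solve(chol, ones))
    total = float(ones @ x)
    return WeightVector(weights=x / total, variance_of_combination=1.0 / total)


def _normal_interval(estimate: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)


def pooled_estimate(
    input: MetaInput, assume_known_sigma: bool = False, level: float = 0.95
) -> LocationResult:
    """Precision-weighted pooled estimate of the average effect.

    Computes ``sum(se_i**-2 beta_i) / sum(se_i**-2)`` with standard error
    ``Phi**-0.5`` and a two-sided normal-quantile interval.  The arithmetic is
    identical whether the ``se`` column holds known sigmas or plug-in
    estimates; ``assume_known_sigma`` only sets the method tag (``known_sigma``
    vs ``naive``) recording which interpretation is claimed.
    """
    wv = inverse_variance_weights(input.se)
    est = float(wv.weights @ input.estimate)
    se = float(np.sqrt(wv.variance_of_combination))
    return LocationResult(
        estimate=est,
        se=se,
        ci=_normal_interval(est, se, level),
        level=level,
        method="known_sigma" if assume_known_sigma else "naive",
    )


def dersimonian_laird(input: MetaInput, level: float = 0.95) -> RandomEffectsResult:
    """DerSimonian-Laird random-effects estimate of (mu, tau-squared).

    The between-study variance is the moment estimator
    ``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w**2)/sum(w)))`` with
    ``w_i = se_i**-2``; the mean uses weights ``1/(se_i**2 + tau2)`` and a
    normal-quantile interval.
    """
    w = input.se**-2.0
    beta = input.estimate
    beta_f = float(w @ beta / w.sum())
    q = float(w @ (beta - beta_f) ** 2)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (input.k - 1)) / denom)
    w_re = 1.0 / (input.se**2 + tau2)
    mu = float(w_re @ beta / w_re.sum())
    se = float(1.0 / np.sqrt(w_re.sum()))
    return RandomEffectsResult(
        mu_hat=mu,
        tau2_hat=float(tau2),
        se=se,
        ci=_normal_interval(mu, se, level),
        level=level,
    )
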