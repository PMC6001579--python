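"""Study-table I/O, the analysis orchestrator, and synthetic fixtures.

Input is a delimited text table (RFC-4180 CSV, UTF-8, header required) with
one row per study and columns ``study_id, estimate, se, n, variance_model,
df_resid`` plus optional ``n1, n2, var1, var2`` for Welch-type studies.
Output is a plain-text report and a deterministic JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    LocationResult,
    MetaInput,
    RandomEffectsResult,
    StudySummary,
    dersimonian_laird,
    pooled_estimate,
    validate_input,
)
from .heterogeneity import HeterogeneityResult, heterogeneity_summary
from .inflation import lssa_interval
from .pboot import ZetaIntervalResult, boot_beta_interval, boot_zeta_interval, draw_bootstrap
from .quasif import quasi_f_interval
from .simstudy import make_scenario, simulate_summaries

__all__ = [
    "REQUIRED_COLUMNS",
    "AnalysisConfig",
    "AnalysisReport",
    "read_studies",
    "write_studies",
    "analyze",
    "make_fixture",
    "FIXTURE_KINDS",
]

REQUIRED_COLUMNS = ("study_id", "estimate", "se", "n", "variance_model", "df_resid")
_GROUP_COLUMNS = ("n1", "n2", "var1", "var2")

#: Interval methods the orchestrator understands (location + heterogeneity).
DEFAULT_METHODS = ("naive", "lssa", "quasi_f", "boot_percentile", "noncentral_chi2")

FIXTURE_KINDS = ("homogeneous", "heterogeneous_6study", "tiny")


def _row_to_study(row: pd.Series, index: int) -> StudySummary:
    def num(col, cast=float, required=True):
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            if required:
                raise ValueError(f"row {index}: missing value in column {col!r}")
            return None
        try:
            return cast(val)
        except (TypeError, ValueError) as err:
            raise ValueError(
                f"row {index}: cannot parse column {col!r} value {val!r}"
            ) from err

    model = str(row["variance_model"]).strip()
    group_n = group_var = None
    if model == "welch_normal":
        vals = [num(c, required=False) for c in _GROUP_COLUMNS]
        if any(v is None for v in vals):
            raise ValueError(
                f"row {index}: welch_normal requires columns {_GROUP_COLUMNS}"
            )
        group_n = (int(vals[0]), int(vals[1]))
        group_var = (vals[2], vals[3])
    try:
        return StudySummary(
            study_id=str(row["study_id"]),
            estimate=num("estimate"),
            se=num("se"),
            n=num("n", cast=lambda v: int(float(v))),
            variance_model=model,
            df_resid=num("df_resid", cast=lambda v: int(float(v)), required=False),
            group_n=group_n,
            group_var=group_var,
        )
    except ValueError as err:
        raise ValueError(f"row {index}: {err}") from err


def read_studies(path: str | Path) -> MetaInput:
    """Read and validate a study-summary CSV into a :class:`MetaInput`."""
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    studies = [_row_to_study(row, i) for i, (_, row) in enumerate(frame.iterrows())]
    return validate_input(studies)


def write_studies(input: MetaInput, path: str | Path) -> None:
    """Write a :class:`MetaInput` back to the CSV study-table format."""
    rows = []
    for s in input.studies:
        row = {
            "study_id": s.study_id,
            "estimate": s.estimate,
            "se": s.se,
            "n": s.n,
            "variance_model": s.variance_model,
            "df_resid": s.df_resid if s.df_resid is not None else "",
        }
        if s.group_n is not None:
            row.update(n1=s.group_n[0], n2=s.group_n[1],
                       var1=s.group_var[0], var2=s.group_var[1])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisConfig:
    methods: tuple[str, ...] = DEFAULT_METHODS
    level: float = 0.95
    B: int = 2000
    seed: int = 0


@dataclass(frozen=True)
class AnalysisReport:
    """Per-method interval results plus provenance for one analysis run."""

    input: MetaInput
    location: dict[str, LocationResult]
    heterogeneity: HeterogeneityResult | None
    zeta_intervals: dict[str, ZetaIntervalResult]
    random_effects: RandomEffectsResult | None
    config: AnalysisConfig

    def to_dict(self) -> dict:
        def loc(r: LocationResult) -> dict:
            return {
                "estimate": r.estimate, "se": r.se, "ci": list(r.ci),
                "level": r.level, "method": r.method,
                "ref_df": None if np.isinf(r.ref_df) else r.ref_df,
            }

        out: dict = {
            "provenance": {
                "package": "femeta", "version": __version__,
                "level": self.config.level, "B": self.config.B,
                "seed": self.config.seed, "methods": list(self.config.methods),
            },
            "input": [
                {"study_id": s.study_id, "estimate": s.estimate, "se": s.se,
                 "n": s.n, "variance_model": s.variance_model,
                 "df_resid": s.df_resid}
                for s in self.input.studies
            ],
            "location": {m: loc(r) for m, r in self.location.items()},
        }
        if self.heterogeneity is not None:
            h = self.heterogeneity
            out["heterogeneity"] = {
                "Q": h.Q, "df": h.df, "I2": h.I2, "zeta2_raw": h.zeta2_raw,
                "zeta2": h.zeta2, "Phi": h.Phi,
                "ci": list(h.ci) if h.ci else None,
                "level": h.level, "method": h.method,
            }
        if self.zeta_intervals:
            out["zeta2_intervals"] = {
                m: {"zeta2": r.zeta2, "ci": list(r.ci), "level": r.level,
                    "method": r.method}
                for m, r in self.zeta_intervals.items()
            }
        if self.random_effects is not None:
            r = self.random_effects
            out["random_effects"] = {
                "mu_hat": r.mu_hat, "tau2_hat": r.tau2_hat, "se": r.se,
                "ci": list(r.ci), "level": r.level, "method": r.method,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"femeta {__version__} — fixed-effects meta-analysis of "
                 f"{self.input.k} studies (N={self.input.N}, "
                 f"Phi={self.input.Phi:.4g})"]
        for m, r in self.location.items():
            lines.append(
                f"  beta_F [{m:>15s}] {r.estimate:+.4f}  "
                f"{r.level:.0%} CI ({r.ci[0]:+.4f}, {r.ci[1]:+.4f})"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"  Q = {h.Q:.3f} on {h.df} df, I2 = {h.I2:.1%}, "
                f"zeta2 = {h.zeta2:.4f}"
            )
            if h.ci is not None:
                lines.append(
                    f"  zeta2 [{h.method:>15s}] {h.level:.0%} CI "
                    f"({h.ci[0]:.4f}, {h.ci[1]:.4f})"
                )
        for m, r in self.zeta_intervals.items():
            lines.append(
                f"  zeta2 [{m:>15s}] {r.level:.0%} CI "
                f"({r.ci[0]:.4f}, {r.ci[1]:.4f})"
            )
        if self.random_effects is not None:
            r = self.random_effects
            lines.append(
                f"  random effects: mu = {r.mu_hat:+.4f} "
                f"CI ({r.ci[0]:+.4f}, {r.ci[1]:+.4f}), tau2 = {r.tau2_hat:.4f}"
            )
        return "\n".join(lines)


def analyze(input: MetaInput, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run the requested interval methods on one meta-analysis input.

    Deterministic given the config seed (bootstrap methods share one draw
    set).  Location methods: naive / known_sigma / lssa / quasi_f /
    dersimonian_laird / the four bootstrap tags; heterogeneity:
    noncentral_chi2 / zeta2_boot_normal / zeta2_boot_percentile.
    """
    location: dict[str, LocationResult] = {}
    zeta: dict[str, ZetaIntervalResult] = {}
    het = None
    random_effects = None
    boot_methods = [m for m in config.methods
                    if m.startswith("boot_") or m.startswith("zeta2_boot")]
    draws = (
        draw_bootstrap(input, config.B, config.seed) if boot_methods else None
    )
    het = heterogeneity_summary(
        input, config.level, with_ci="noncentral_chi2" in config.methods
    )
    for m in config.methods:
        if m in ("naive", "known_sigma"):
            location[m] = pooled_estimate(
                input, assume_known_sigma=(m == "known_sigma"), level=config.level
            )
        elif m == "lssa":
            location[m] = lssa_interval(input, config.level)
        elif m == "quasi_f":
            location[m] = quasi_f_interval(input, config.level)
        elif m == "dersimonian_laird":
            random_effects = dersimonian_laird(input, config.level)
        elif m.startswith("zeta2_boot_"):
            zeta[m] = boot_zeta_interval(
                draws, het.zeta2, config.level, m.removeprefix("zeta2_")
            )
        elif m.startswith("boot_"):
            location[m] = boot_beta_interval(draws, input, config.level, m)
        elif m == "noncentral_chi2":
            pass  # carried on the heterogeneity summary
        else:
            raise ValueError(f"unknown method {m!r}")
    return AnalysisReport(
        input=input, location=location, heterogeneity=het,
        zeta_intervals=zeta, random_effects=random_effects, config=config,
    )


def make_fixture(
    kind: str, seed: int = 0, out: str | Path | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic study table with known generating truth.

    Kinds: ``homogeneous`` (k=5, zeta2=0), ``heterogeneous_6study`` (a
    synthetic 6-study mean-difference meta-analysis with substantial
    heterogeneity, on a days-of-symptoms-like scale), ``tiny`` (k=3, small).
    When ``out`` is given, writes the CSV there and the truth sidecar to
    ``<out>.truth.json``.  Same kind and seed always reproduce identical
    files.
    """
    if kind == "homogeneous":
        scenario = make_scenario(k=5, n=40, zeta2_true=0.0, beta_F_true=0.5,
                                 sigma2_within=1.0, seed=seed)
    elif kind == "heterogeneous_6study":
        scenario = make_scenario(k=6, n=50, zeta2_true=2.0, beta_F_true=-2.0,
                                 sigma2_within=6.25, seed=seed)
    elif kind == "tiny":
        scenario = make_scenario(k=3, n=10, zeta2_true=0.25, beta_F_true=0.0,
                                 sigma2_within=1.0, seed=seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of "
                         f"{FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    meta = simulate_summaries(scenario, rng)
    truth = {
        "kind": kind, "seed": seed, "k": scenario.k, "n": scenario.n,
        "beta_F_true": scenario.beta_F_true, "zeta2_true": scenario.zeta2_true,
        "sigma2_within": scenario.sigma2_within,
        "true_betas": list(scenario.true_betas),
        "synthetic": True,
    }
    frame = pd.DataFrame(
        {
            "study_id": [s.study_id for s in meta.studies],
            "estimate": [s.estimate for s in meta.studies],
            "se": [s.se for s in meta.studies],
            "n": [s.n for s in meta.studies],
            "variance_model": [s.variance_model for s in meta.studies],
            "df_resid": [s.df_resid for s in meta.studies],
        }
    )
    if out is not None:
        out = Path(out)
        frame.to_csv(out, index=False)
        out.with_suffix(out.suffix + ".truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True)
        )
    return frame, truth
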