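"""Bootstrap confidence intervals and the study's sensitivity analyses.

Uncertainty in PAF/PIF estimates is quantified by a nonparametric bootstrap
with percentile confidence intervals taken from the empirical distribution of
replicate estimates; the point estimate always comes from the unresampled
data. Three resampling units are supported:

``country``
    Countries drawn with replacement; regressions refitted and the scenario/
    attribution pipeline rerun per replicate. A country drawn twice enters as
    two distinct panel units. Appropriate for regional and HDI-level CIs.
``country_panel_rows``
    Each country's fitting-year rows resampled with replacement (coefficient
    uncertainty without dropping countries).
``rr_lognormal``
    Each relative risk redrawn from a lognormal matched to its published 95%
    CI (RR uncertainty only; regressions untouched). Usable for per-country
    CIs, where resampling countries is incoherent.

Sensitivity analyses: projected incidence scaled by a constant factor
(e.g. 0.9 / 1.1), which scales all case counts exactly and leaves PAF/PIF
untouched; and the MPOWER x literacy interaction model, whose combined
scenario uses country-specific marginal policy effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .attribution import COUNT_COLUMNS
from .errors import BootstrapError, ConfigurationError, DomainError
from .panel import PolicyPanel, RelativeRiskTable
from .regression import INTERACTION_TERM, FixedEffectsPanelResults

RESAMPLE_UNITS = ("country", "country_panel_rows", "rr_lognormal")


@dataclass
class BootstrapConfig:
    """Settings for the nonparametric bootstrap (defaults: 1,000 replicates,
    95% percentile intervals, country-level resampling)."""

    n_reps: int = 1000
    seed: int = 0
    resample_unit: str = "country"
    ci_level: float = 0.95
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.resample_unit not in RESAMPLE_UNITS:
            raise ValueError(f"resample_unit must be one of {RESAMPLE_UNITS}")


@dataclass
class BootstrapResult:
    """Point estimate with percentile bounds; ``draws`` holds the replicate
    statistics (rows = replicates) for diagnostics."""

    point: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_reps: int
    n_failed: int
    ci_level: float
    draws: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def bootstrap_ci(
    statistic: Callable[[np.random.Generator | None], "pd.Series | float | Mapping[str, float]"],
    config: BootstrapConfig,
) -> BootstrapResult:
    """Generic percentile-bootstrap engine.

    ``statistic(None)`` must return the unresampled point estimate;
    ``statistic(rng)`` one replicate, resampling internally with ``rng``.
    Each replicate gets an independent seeded substream spawned from the
    master seed, so replicates are order-independent. Failing replicates are
    dropped and counted; more than ``max_failure_fraction`` failures aborts.
    """
    raw_point = statistic(None)
    scalar = not isinstance(raw_point, (pd.Series, Mapping))
    point = _as_series(raw_point)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    draws = []
    n_failed = 0
    for ss in seeds:
        try:
            rep = statistic(np.random.default_rng(ss))
            draws.append(float(rep) if scalar else _as_series(rep))
        except Exception:
            n_failed += 1
    if n_failed > config.max_failure_fraction * config.n_reps:
        raise BootstrapError(
            f"{n_failed}/{config.n_reps} bootstrap replicates failed "
            f"(> {config.max_failure_fraction:.0%} allowed)")
    alpha = (1.0 - config.ci_level) / 2.0
    if scalar:
        arr = np.asarray(draws, dtype=float)
        lo = pd.Series({point.index[0]: np.quantile(arr, alpha)})
        hi = pd.Series({point.index[0]: np.quantile(arr, 1.0 - alpha)})
        draw_df = pd.DataFrame({point.index[0]: arr})
    else:
        draw_df = pd.DataFrame(draws).reindex(columns=point.index)
        lo = draw_df.quantile(alpha)
        hi = draw_df.quantile(1.0 - alpha)
    return BootstrapResult(point=point, ci_low=lo, ci_high=hi,
                           n_reps=config.n_reps, n_failed=n_failed,
                           ci_level=config.ci_level, draws=draw_df)


def _as_series(value) -> pd.Series:
    if isinstance(value, pd.Series):
        return value.astype(float)
    if isinstance(value, Mapping):
        return pd.Series(value, dtype=float)
    return pd.Series({"statistic": float(value)})


# ---------------------------------------------------------------------------
# Resamplers
# ---------------------------------------------------------------------------

def resample_countries(panel: PolicyPanel, anchors: pd.DataFrame,
                       rng: np.random.Generator,
                       hdi: Mapping[str, str] | None = None,
                       ) -> tuple[PolicyPanel, pd.DataFrame, dict[str, str] | None]:
    """Draw countries with replacement; duplicates are relabelled ``Name#k`` so
    the fixed-effects design and the stratum keys treat them as distinct
    units. Panel, anchors, and HDI map are relabelled consistently."""
    countries = sorted(panel.data["country"].unique())
    drawn = rng.choice(countries, size=len(countries), replace=True)
    counts: dict[str, int] = {}
    panel_parts, anchor_parts = [], []
    new_hdi: dict[str, str] = {}
    for name in drawn:
        counts[name] = counts.get(name, 0) + 1
        label = name if counts[name] == 1 else f"{name}#{counts[name]}"
        p = panel.data[panel.data["country"] == name].copy()
        p["country"] = label
        panel_parts.append(p)
        a = anchors[anchors["country"] == name].copy()
        a["country"] = label
        anchor_parts.append(a)
        if hdi is not None:
            new_hdi[label] = hdi[name]
    new_panel = PolicyPanel(pd.concat(panel_parts, ignore_index=True),
                            fit_years=panel.fit_years)
    new_anchors = pd.concat(anchor_parts, ignore_index=True)
    return new_panel, new_anchors, (new_hdi if hdi is not None else None)


def resample_panel_rows(panel: PolicyPanel, rng: np.random.Generator) -> PolicyPanel:
    """Resample each (country, gender)'s fitting-year rows with replacement,
    keeping baseline (non-fitting-year) rows intact. Resampled rows are
    re-keyed to the original year grid so panel invariants hold."""
    fit_years = sorted(panel.fit_years)
    parts = []
    for (_, _), grp in panel.data.groupby(["country", "gender"], sort=True):
        fit_rows = grp[grp["year"].isin(fit_years)].sort_values("year")
        other = grp[~grp["year"].isin(fit_years)]
        if len(fit_rows):
            take = rng.integers(0, len(fit_rows), size=len(fit_rows))
            res = fit_rows.iloc[take].copy()
            res["year"] = [int(y) for y in fit_rows["year"].iloc[: len(res)]]
            parts.append(res)
        parts.append(other)
    return PolicyPanel(pd.concat(parts, ignore_index=True), fit_years=panel.fit_years)


def resample_rr_lognormal(rr: RelativeRiskTable, rng: np.random.Generator,
                          z: float = 1.959963984540054) -> RelativeRiskTable:
    """Redraw each RR from a lognormal with median at the point estimate and
    log-SD matched to its 95% CI: sigma = (ln hi - ln lo) / (2 z). Rows
    without CI bounds are kept fixed."""
    df = rr.data.copy()
    has_ci = df["ci_low"].notna() & df["ci_high"].notna() & (df["ci_low"] > 0)
    sigma = np.zeros(len(df))
    sigma[has_ci.to_numpy()] = (
        (np.log(df.loc[has_ci, "ci_high"]) - np.log(df.loc[has_ci, "ci_low"])) / (2 * z)
    )
    draw = np.exp(np.log(df["rr"].to_numpy()) + sigma * rng.standard_normal(len(df)))
    df["rr"] = np.where(has_ci, draw, df["rr"])
    out = RelativeRiskTable.__new__(RelativeRiskTable)  # skip re-validation cost
    out.data = df
    out.fallbacks = []
    return out


# ---------------------------------------------------------------------------
# Incidence-scaling sensitivity
# ---------------------------------------------------------------------------

def scale_incidence(results: pd.DataFrame, factor: float) -> pd.DataFrame:
    """Scale all case-count columns by ``factor`` (> 0). PAF/PIF columns are
    ratios of counts and are left untouched; scaling therefore commutes
    exactly with aggregation."""
    if not factor > 0:
        raise DomainError(f"incidence scale factor must be > 0, got {factor}")
    out = results.copy()
    for col in COUNT_COLUMNS:
        if col in out.columns:
            out[col] = out[col] * factor
    if "cases" in out.columns:  # raw anchor/series frames
        out["cases"] = out["cases"] * factor
    return out


# ---------------------------------------------------------------------------
# MPOWER x literacy interaction sensitivity
# ---------------------------------------------------------------------------

def interaction_marginal_effects(
    fit: FixedEffectsPanelResults,
    policy_values: pd.DataFrame,
) -> pd.DataFrame:
    """Country-specific marginal policy effects from the interaction model.

    With the uncentered product term, d(prevalence)/d(mpower) =
    beta_mpower + beta_inter * literacy and d/d(literacy) =
    beta_literacy + beta_inter * mpower, evaluated at each country's own
    covariate values; the affordability effect is unmodified.

    ``policy_values`` needs columns ``country, mpower, literacy`` (one
    gender's rows). Returns a frame indexed by country with columns
    ``mpower, affordability, literacy``.
    """
    if INTERACTION_TERM not in fit.params.index:
        raise ConfigurationError(
            "fit has no mpower:literacy term; fit the interaction model first")
    b = fit.params
    out = pd.DataFrame(index=pd.Index(policy_values["country"], name="country"))
    lit = policy_values["literacy"].to_numpy(dtype=float)
    mp = policy_values["mpower"].to_numpy(dtype=float)
    out["mpower"] = b["mpower"] + b[INTERACTION_TERM] * lit
    out["affordability"] = b["affordability"]
    out["literacy"] = b["literacy"] + b[INTERACTION_TERM] * mp
    return out
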