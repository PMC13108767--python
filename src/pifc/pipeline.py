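"""End-to-end policy-impact model: panel regression -> scenarios -> attribution.

:class:`TobaccoPolicyModel` bundles the four input tables (policy panel,
incidence anchors, relative risks, HDI grouping); :meth:`~TobaccoPolicyModel.fit`
fits the gender-specific fixed-effects regressions, builds the counterfactual
scenario prevalences, annualises the incidence anchors, and computes
stratum-level attribution. The returned :class:`TobaccoPolicyResults` exposes
aggregation at any level, percentile-bootstrap confidence intervals, the
incidence-scaling sensitivity, and summary tables.

:func:`run_full_pipeline` is the one-command reproduction driver used by the
CLI: it resolves a :class:`RunConfig`, runs the model, and writes every output
table (plus the resolved configuration and a run log) to the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .attribution import aggregate, attribution_table
from .constants import (
    BASELINE_YEAR,
    GENDERS,
    PROJECTION_END,
    PROJECTION_START,
    SCENARIOS,
)
from .errors import ConfigurationError
from .incidence import annualize, cumulative_cases
from .panel import (
    PolicyPanel,
    RelativeRiskTable,
    check_hdi_coverage,
    default_hdi_map,
    load_hdi_map,
    load_incidence_anchors,
    load_policy_panel,
    load_rr_table,
)
from .regression import FixedEffectsPanelResults, fit_all_models
from .scenarios import ScenarioCoefficients, build_scenario_table
from .uncertainty import (
    BootstrapConfig,
    bootstrap_ci,
    interaction_marginal_effects,
    resample_countries,
    resample_panel_rows,
    resample_rr_lognormal,
    scale_incidence,
)

logger = logging.getLogger("pifc")

_CI_METRICS = ("pif", "preventable_cases")


@dataclass
class RunConfig:
    """Plain-text-serialisable configuration of one full pipeline run."""

    panel: str
    anchors: str
    rr: str
    hdi: str | None = None
    scenarios: tuple[str, ...] = SCENARIOS
    baseline_year: int = BASELINE_YEAR
    year_from: int = PROJECTION_START
    year_to: int = PROJECTION_END
    incidence_scale: float = 1.0
    interaction: bool = False
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 20250101
    bootstrap: bool = True
    ci_level: float = 0.95
    output_dir: str = "results"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.scenarios = tuple(cfg.scenarios)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scenarios"] = list(self.scenarios)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class TobaccoPolicyModel:
    """Policy-scenario model of preventable tobacco-related cancers.

    Parameters
    ----------
    panel
        Policy panel with fitting-year rows and ``baseline_year`` rows.
    anchors
        Validated 5-year projected-case anchors per (country, gender, site).
    rr
        Relative-risk table for current smoking per (site, gender).
    hdi
        Country -> {low, medium, high} map for post-estimation aggregation
        (defaults to the canonical 16-country grouping when it covers the
        panel's countries, else no HDI aggregation).
    interaction
        If True, the combined scenario uses country-specific marginal effects
        from the MPOWER x literacy interaction model instead of the plain
        multivariable coefficients.
    """

    def __init__(
        self,
        panel: PolicyPanel,
        anchors: pd.DataFrame,
        rr: RelativeRiskTable,
        hdi: Mapping[str, str] | None = None,
        baseline_year: int = BASELINE_YEAR,
        year_from: int = PROJECTION_START,
        year_to: int = PROJECTION_END,
        interaction: bool = False,
    ):
        self.panel = panel
        self.anchors = anchors
        self.rr = rr
        if hdi is None:
            candidate = default_hdi_map()
            hdi = candidate if set(panel.countries) <= set(candidate) else None
        if hdi is not None:
            check_hdi_coverage(hdi, panel.countries)
        self.hdi = dict(hdi) if hdi is not None else None
        self.baseline_year = baseline_year
        self.year_from = year_from
        self.year_to = year_to
        self.interaction = interaction

    @classmethod
    def from_files(cls, panel: str | Path, anchors: str | Path, rr: str | Path,
                   hdi: str | Path | None = None, **kwargs) -> "TobaccoPolicyModel":
        return cls(
            load_policy_panel(panel),
            load_incidence_anchors(anchors),
            load_rr_table(rr),
            load_hdi_map(hdi) if hdi else None,
            **kwargs,
        )

    # -- fitting -------------------------------------------------------------
    def fit(self) -> "TobaccoPolicyResults":
        models = ("m1", "m2", "m3", "m4") + (("m4x",) if self.interaction else ())
        fits = {g: fit_all_models(self.panel, g, models) for g in GENDERS}
        series = annualize(self.anchors)
        cumulative = cumulative_cases(series, self.year_from, self.year_to)
        scenario_prev, strata = self._scenarios_and_strata(self.panel, fits, cumulative, self.rr)
        return TobaccoPolicyResults(
            model=self,
            fits=fits,
            scenario_prevalence=scenario_prev,
            incidence_series=series,
            cumulative=cumulative,
            strata=strata,
        )

    def _scenarios_and_strata(self, panel: PolicyPanel,
                              fits: Mapping[str, Mapping[str, FixedEffectsPanelResults]],
                              cumulative: pd.DataFrame,
                              rr: RelativeRiskTable,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
        coeffs = {g: ScenarioCoefficients.from_fits(fits[g], g) for g in GENDERS}
        marginals = None
        if self.interaction:
            marginals = {}
            for g in GENDERS:
                vals = panel.latest_policy_values(prefer_year=self.baseline_year)
                marginals[g] = interaction_marginal_effects(
                    fits[g]["m4x"], vals[vals["gender"] == g])
        scenario_prev = build_scenario_table(
            panel, coeffs, baseline_year=self.baseline_year,
            marginal_coefficients=marginals)
        strata = attribution_table(scenario_prev, rr, cumulative)
        return scenario_prev, strata


@dataclass
class TobaccoPolicyResults:
    """Fitted pipeline state plus aggregation, bootstrap, and sensitivity APIs."""

    model: TobaccoPolicyModel
    fits: dict[str, dict[str, FixedEffectsPanelResults]]
    scenario_prevalence: pd.DataFrame
    incidence_series: pd.DataFrame
    cumulative: pd.DataFrame
    strata: pd.DataFrame
    ci_tables: dict[tuple[str, ...], pd.DataFrame] = field(default_factory=dict)

    # -- aggregation ---------------------------------------------------------
    def by(self, *keys: str) -> pd.DataFrame:
        return aggregate(self.strata, by=list(keys), hdi=self.model.hdi)

    def by_country(self) -> pd.DataFrame:
        return self.by("country")

    def by_site(self) -> pd.DataFrame:
        return self.by("site")

    def by_hdi(self) -> pd.DataFrame:
        return self.by("hdi_group")

    def regional(self) -> pd.DataFrame:
        return self.by("region")

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for gender, models in self.fits.items():
            for name, res in models.items():
                frame = res.to_frame()
                frame.insert(0, "model", name)
                rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    # -- sensitivity ---------------------------------------------------------
    def scale_incidence(self, factor: float) -> dict[str, pd.DataFrame]:
        """Attribution tables with projected incidence scaled by ``factor``;
        PAF/PIF are unchanged, all case counts scale exactly."""
        strata = scale_incidence(self.strata, factor)
        return {
            "strata": strata,
            "country": aggregate(strata, ["country"], self.model.hdi),
            "site": aggregate(strata, ["site"], self.model.hdi),
            "region": aggregate(strata, ["region"], self.model.hdi),
        }

    # -- bootstrap -----------------------------------------------------------
    def bootstrap(self, config: BootstrapConfig,
                  by: Sequence[Sequence[str]] = (("region",),),
                  ) -> dict[tuple[str, ...], pd.DataFrame]:
        """Attach percentile CIs to aggregated PIFs and preventable counts.

        ``by`` lists the aggregation levels to cover in one resampling pass,
        e.g. ``[("region",), ("hdi_group",), ("site",)]``. Returns (and caches
        in :attr:`ci_tables`) one table per level with ``*_ci_low/high``
        columns. Country-keyed levels are rejected under country resampling,
        where replicate country sets differ.
        """
        levels = [tuple(b) for b in by]
        if config.resample_unit == "country":
            for lvl in levels:
                if "country" in lvl:
                    raise ConfigurationError(
                        "country-keyed CIs are incoherent under country "
                        "resampling; use rr_lognormal or country_panel_rows")

        def statistic(rng: np.random.Generator | None) -> pd.Series:
            strata, hdi = self._replicate_strata(rng, config.resample_unit)
            parts = {}
            for lvl in levels:
                agg = aggregate(strata, by=list(lvl), hdi=hdi)
                keys = [k for k in agg.columns if k not in
                        ("pif", "paf_current", *_CI_METRICS, "total_cases",
                         "attributable_cases")]
                for _, row in agg.iterrows():
                    tag = "|".join([*lvl, *(str(row[k]) for k in keys)])
                    for metric in _CI_METRICS:
                        parts[f"{tag}|{metric}"] = float(row[metric])
            return pd.Series(parts)

        result = bootstrap_ci(statistic, config)
        out: dict[tuple[str, ...], pd.DataFrame] = {}
        for lvl in levels:
            agg = aggregate(self.strata, by=list(lvl), hdi=self.model.hdi)
            keys = [k for k in agg.columns if k not in
                    ("pif", "paf_current", *_CI_METRICS, "total_cases",
                     "attributable_cases")]
            for metric in _CI_METRICS:
                lows, highs = [], []
                for _, row in agg.iterrows():
                    tag = "|".join([*lvl, *(str(row[k]) for k in keys)]) + f"|{metric}"
                    lows.append(result.ci_low.get(tag, np.nan))
                    highs.append(result.ci_high.get(tag, np.nan))
                agg[f"{metric}_ci_low"] = lows
                agg[f"{metric}_ci_high"] = highs
            out[lvl] = agg
        self.ci_tables.update(out)
        return out

    def _replicate_strata(self, rng: np.random.Generator | None,
                          unit: str) -> tuple[pd.DataFrame, Mapping[str, str] | None]:
        """One bootstrap replicate's stratum table (rng=None -> point data)."""
        if rng is None:
            return self.strata, self.model.hdi
        m = self.model
        if unit == "country":
            panel, _, hdi = resample_countries(m.panel, m.anchors.iloc[:0], rng, m.hdi)
            # cumulative totals are per-country: relabel the precomputed
            # table instead of re-annualizing identical anchors
            parts = []
            for label in panel.countries:
                src = label.split("#")[0]
                cum = self.cumulative[self.cumulative["country"] == src].copy()
                cum["country"] = label
                parts.append(cum)
            cumulative = pd.concat(parts, ignore_index=True)
            fits = {g: fit_all_models(panel, g, tuple(self.fits[g])) for g in GENDERS}
            _, strata = m._scenarios_and_strata(panel, fits, cumulative, m.rr)
            return strata, hdi
        if unit == "country_panel_rows":
            panel = resample_panel_rows(m.panel, rng)
            fits = {g: fit_all_models(panel, g, tuple(self.fits[g])) for g in GENDERS}
            _, strata = m._scenarios_and_strata(panel, fits, self.cumulative, m.rr)
            return strata, m.hdi
        if unit == "rr_lognormal":
            rr = resample_rr_lognormal(m.rr, rng)
            strata = attribution_table(self.scenario_prevalence, rr, self.cumulative)
            return strata, m.hdi
        raise ValueError(f"unknown resample unit {unit!r}")

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        reg = self.regional()
        lines = [
            "Tobacco-control policy impact model",
            f"countries: {len(self.model.panel.countries)}  "
            f"window: {self.model.year_from}-{self.model.year_to}",
            "",
            f"{'scenario':<22}{'PIF %':>8}{'preventable':>14}{'attributable':>14}{'total':>12}",
        ]
        for _, row in reg.iterrows():
            lines.append(
                f"{row['scenario']:<22}{100 * row['pif']:>8.1f}"
                f"{row['preventable_cases']:>14,.0f}"
                f"{row['attributable_cases']:>14,.0f}"
                f"{row['total_cases']:>12,.0f}"
            )
        lines.append("")
        for gender in GENDERS:
            lines.append(self.fits[gender]["m4"].summary())
            lines.append("")
        return "\n".join(lines)


def _report_rounding(df: pd.DataFrame) -> pd.DataFrame:
    """Report-style copy: counts rounded half-up to integers, fractions to
    percent with 1 decimal. Machine-readable outputs keep full precision."""
    out = df.copy()
    for col in ("total_cases", "attributable_cases", "preventable_cases"):
        if col in out.columns:
            out[col] = np.floor(out[col] + 0.5).astype("int64")
    for col in out.columns:
        if col.startswith(("pif", "paf")):
            out[col] = (100.0 * out[col]).round(1)
    return out


def run_full_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Load inputs, fit, bootstrap, and write every output table.

    Writes to ``config.output_dir``: ``fits.csv``, ``scenario_prevalence.csv``,
    ``country_pif.csv``, ``site_pif.csv``, ``hdi_pif.csv`` (when an HDI map
    applies), ``regional_pif.csv``, report-rounded ``*_report.csv`` variants,
    the resolved config, and ``run.log``. Returns the full-precision tables.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        model = TobaccoPolicyModel.from_files(
            config.panel, config.anchors, config.rr, config.hdi,
            baseline_year=config.baseline_year,
            year_from=config.year_from, year_to=config.year_to,
            interaction=config.interaction,
        )
        logger.info("cumulative window: %d-%d inclusive (%d annual values)",
                    config.year_from, config.year_to,
                    config.year_to - config.year_from + 1)
        logger.info("combined-scenario coefficients: %s",
                    "interaction marginal effects" if config.interaction
                    else "multivariable model")
        results = model.fit()
        if config.incidence_scale != 1.0:
            logger.info("incidence sensitivity scale: %.3f", config.incidence_scale)
            results.strata = scale_incidence(results.strata, config.incidence_scale)
            results.cumulative = scale_incidence(results.cumulative, config.incidence_scale)

        tables: dict[str, pd.DataFrame] = {
            "fits": results.fits_frame(),
            "scenario_prevalence": results.scenario_prevalence,
            "country_pif": results.by_country(),
            "site_pif": results.by_site(),
            "regional_pif": results.regional(),
        }
        if model.hdi is not None:
            tables["hdi_pif"] = results.by_hdi()

        if config.bootstrap:
            levels: list[tuple[str, ...]] = [("region",), ("site",)]
            if model.hdi is not None:
                levels.append(("hdi_group",))
            logger.info("bootstrap: %d reps, unit=country, levels=%s",
                        config.bootstrap_reps, levels)
            ci = results.bootstrap(
                BootstrapConfig(n_reps=config.bootstrap_reps,
                                seed=config.bootstrap_seed,
                                resample_unit="country",
                                ci_level=config.ci_level),
                by=levels)
            tables["regional_pif"] = ci[("region",)]
            tables["site_pif"] = ci[("site",)]
            if ("hdi_group",) in ci:
                tables["hdi_pif"] = ci[("hdi_group",)]
            logger.info("bootstrap: %d reps, unit=rr_lognormal, level=country",
                        config.bootstrap_reps)
            ci_country = results.bootstrap(
                BootstrapConfig(n_reps=config.bootstrap_reps,
                                seed=config.bootstrap_seed + 1,
                                resample_unit="rr_lognormal",
                                ci_level=config.ci_level),
                by=[("country",)])
            tables["country_pif"] = ci_country[("country",)]

        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.17g")
            if name.endswith("_pif"):
                _report_rounding(df).to_csv(out_dir / f"{name}_report.csv", index=False)
        config.to_yaml(out_dir / "resolved_config.yaml")
        if config.plots:
            from .plotting import render_summary_plots
            render_summary_plots(tables, out_dir)
        logger.info("wrote %d tables to %s", len(tables), out_dir)
        return tables
    finally:
        logger.removeHandler(handler)
        handler.close()
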