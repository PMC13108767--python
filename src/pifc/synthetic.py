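"""Synthetic panels, incidence anchors, and RR tables with known ground truth.

The generator emulates the Eastern Mediterranean study conditions: 16 countries
observed biennially 2010-2020 plus a 2025 baseline, gender-specific smoking
prevalence driven linearly by MPOWER score, cigarette affordability, and adult
literacy through country and year fixed effects, and cancer-case projection
anchors at 5-year intervals 2025-2050 that grow exactly linearly within the
window (so annualisation is exact by construction).

Every generated dataset is returned together with its :class:`SyntheticTruth`
so downstream estimators can be checked for exact (noiseless) or unbiased
(noisy) parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ANALYSIS_COUNTRIES,
    ANCHOR_YEARS,
    BASELINE_YEAR,
    FIT_YEARS,
    GENDERS,
    SITES,
    sites_for_gender,
)
from .panel import PolicyPanel, RelativeRiskTable, validate_anchor_frame

# Study-condition defaults: true policy coefficients in percentage points of
# prevalence per predictor unit. The MPOWER slope sits at the regional
# ceiling of -0.26 pp per score unit; women's prevalence responds on a
# smaller absolute scale, matching their far lower baseline prevalence.
DEFAULT_BETA = {
    "men": {"mpower": -0.26, "affordability": -0.18, "literacy": -0.20},
    "women": {"mpower": -0.10, "affordability": -0.07, "literacy": -0.08},
}
DEFAULT_INTERCEPT = {"men": 65.0, "women": 22.0}
DEFAULT_COUNTRY_EFFECT_SD = {"men": 4.0, "women": 2.0}


@dataclass
class SyntheticTruth:
    """Ground-truth parameters recorded alongside every generated dataset."""

    beta: dict[str, dict[str, float]]
    intercept: dict[str, float]
    country_effects: dict[str, dict[str, float]]
    year_effects: dict[str, dict[int, float]]
    noise_sd: float
    clipped_fraction: float = 0.0
    growth: dict | None = None
    interaction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_panel(
    n_countries: int = 16,
    years: tuple[int, ...] = FIT_YEARS + (BASELINE_YEAR,),
    fit_years: tuple[int, ...] = FIT_YEARS,
    beta: dict[str, dict[str, float]] | None = None,
    intercept: dict[str, float] | None = None,
    interaction: dict[str, float] | None = None,
    country_effect_sd: float | dict[str, float] | None = None,
    year_effect_sd: float = 0.8,
    noise_sd: float = 1.0,
    mpower_literacy_rho: float = 0.3,
    seed: int = 0,
) -> tuple[PolicyPanel, SyntheticTruth]:
    """Generate a gender-stratified policy panel from a known linear model.

    Prevalence for country *i*, year *t*, gender *g* is

        b0_g + sum_k beta_gk * x_itk [+ b_x * mpower * literacy]
             + country_effect_gi + year_effect_gt + Normal(0, noise_sd),

    clipped to [0, 100]. Predictors are drawn in realistic regional ranges
    (MPOWER integer 20-31, affordability 0-15 % of GDP per capita, literacy
    30-100 %) with mild positive MPOWER-literacy correlation so collinearity
    diagnostics and the interaction sensitivity have realistic structure.
    MPOWER and affordability drift slowly upward within a country over time,
    giving the within-country variation the fixed-effects estimator needs.

    Deterministic given ``seed``; no global random state is touched. The
    fraction of clipped prevalence values is recorded in the returned truth,
    and a warning is raised when it exceeds 5 % (bias hazard for recovery
    tests).
    """
    if n_countries < 2:
        raise ValueError("need at least 2 countries")
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    beta = beta if beta is not None else {g: dict(DEFAULT_BETA[g]) for g in GENDERS}
    intercept = intercept if intercept is not None else dict(DEFAULT_INTERCEPT)
    interaction = dict(interaction or {})
    # country heterogeneity scales with each gender's prevalence range:
    # men span ~0-60%, women ~0-26%, so women's between-country spread is tighter
    if country_effect_sd is None:
        country_effect_sd = dict(DEFAULT_COUNTRY_EFFECT_SD)
    if not isinstance(country_effect_sd, dict):
        country_effect_sd = {g: float(country_effect_sd) for g in GENDERS}

    rng = np.random.default_rng(seed)
    if n_countries <= len(ANALYSIS_COUNTRIES):
        countries = list(ANALYSIS_COUNTRIES[:n_countries])
    else:
        countries = list(ANALYSIS_COUNTRIES) + [
            f"Country{i:02d}" for i in range(n_countries - len(ANALYSIS_COUNTRIES))
        ]
    years = tuple(int(y) for y in years)

    # Country-level baseline policy draws shared by both genders.
    lit_base = rng.uniform(30.0, 95.0, n_countries)
    # MPOWER correlated with literacy via a Gaussian copula on ranks.
    z_lit = (lit_base - lit_base.mean()) / (lit_base.std() + 1e-12)
    z_ind = rng.standard_normal(n_countries)
    z_mp = mpower_literacy_rho * z_lit + np.sqrt(max(0.0, 1 - mpower_literacy_rho**2)) * z_ind
    mp_base = 20 + (z_mp - z_mp.min()) / (np.ptp(z_mp) + 1e-12) * 9.0  # spread over 20-29
    aff_base = rng.uniform(0.5, 8.0, n_countries)

    rows = []
    truth_country: dict[str, dict[str, float]] = {}
    truth_year: dict[str, dict[int, float]] = {}
    n_clipped = 0
    n_total = 0
    for gender in GENDERS:
        c_eff = rng.normal(0.0, country_effect_sd[gender], n_countries)
        c_eff -= c_eff[0]  # reference-cell parameterisation: first country = 0
        y_eff = rng.normal(0.0, year_effect_sd, len(years))
        y_eff -= y_eff[0]
        truth_country[gender] = dict(zip(countries, c_eff))
        truth_year[gender] = dict(zip(years, y_eff))
        b = beta[gender]
        b_x = interaction.get(gender, 0.0)
        for ci, country in enumerate(countries):
            # slow within-country policy improvement over calendar time
            mp_slope = rng.uniform(0.2, 0.8)
            aff_slope = rng.uniform(0.05, 0.35)
            lit_slope = rng.uniform(0.2, 0.8)
            for yi, year in enumerate(years):
                dt = (year - years[0]) / 2.0
                mpower = int(np.clip(round(mp_base[ci] + mp_slope * dt), 20, 31))
                afford = float(np.clip(aff_base[ci] + aff_slope * dt, 0.0, 15.0))
                lit = float(np.clip(lit_base[ci] + lit_slope * dt, 30.0, 100.0))
                mean = (
                    intercept[gender]
                    + b["mpower"] * mpower
                    + b["affordability"] * afford
                    + b["literacy"] * lit
                    + b_x * mpower * lit
                    + c_eff[ci]
                    + y_eff[yi]
                )
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                prev = mean + noise
                clipped = np.clip(prev, 0.0, 100.0)
                n_clipped += int(clipped != prev)
                n_total += 1
                rows.append(
                    {
                        "country": country,
                        "year": year,
                        "gender": gender,
                        "prevalence": float(clipped),
                        "mpower": mpower,
                        "affordability": afford,
                        "literacy": lit,
                    }
                )

    clipped_fraction = n_clipped / n_total
    if clipped_fraction > 0.05:
        warnings.warn(
            f"{clipped_fraction:.1%} of prevalence values clipped to [0, 100]; "
            "recovery estimates will be biased",
            stacklevel=2,
        )
    panel = PolicyPanel(pd.DataFrame(rows), fit_years=fit_years)
    truth = SyntheticTruth(
        beta=beta,
        intercept=intercept,
        country_effects=truth_country,
        year_effects=truth_year,
        noise_sd=noise_sd,
        clipped_fraction=clipped_fraction,
        interaction=interaction,
    )
    return panel, truth


def generate_anchors(
    countries: list[str] | None = None,
    sites: tuple[str, ...] = SITES,
    base_cases: float = 1000.0,
    growth: float = 0.04,
    seed: int = 0,
    anchor_years: tuple[int, ...] = ANCHOR_YEARS,
) -> pd.DataFrame:
    """Projected-case anchors growing exactly linearly from a 2025 base.

    ``cases(year) = base * (1 + growth * (year - 2025))`` per stratum, with the
    stratum base drawn log-uniformly in [0.2, 5] x ``base_cases`` so country
    and site totals differ. Cervix anchors are emitted for women only.
    """
    if base_cases <= 0:
        raise ValueError("base_cases must be > 0")
    countries = countries if countries is not None else list(ANALYSIS_COUNTRIES)
    horizon = max(anchor_years) - min(anchor_years)
    if 1 + growth * horizon < 0:
        raise ValueError(f"growth {growth} drives cases negative by {max(anchor_years)}")

    rng = np.random.default_rng(seed)
    rows = []
    for country in countries:
        for gender in GENDERS:
            for site in sites:
                if site not in sites_for_gender(gender):
                    continue
                base = base_cases * float(np.exp(rng.uniform(np.log(0.2), np.log(5.0))))
                for year in anchor_years:
                    rows.append(
                        {
                            "country": country,
                            "gender": gender,
                            "site": site,
                            "year": year,
                            "cases": base * (1.0 + growth * (year - min(anchor_years))),
                        }
                    )
    return validate_anchor_frame(pd.DataFrame(rows), anchor_years=anchor_years)


def generate_rr_table(
    sites: tuple[str, ...] = SITES,
    seed: int = 0,
    rr_range: tuple[float, float] = (1.1, 10.0),
    ci_relative_width: float = 0.25,
) -> RelativeRiskTable:
    """Relative risks sampled log-uniformly in ``rr_range`` per (site, gender).

    95% CI bounds are attached at +/- ``ci_relative_width`` on the log scale,
    giving the lognormal-resampling bootstrap something realistic to draw from.
    Cervix gets a women-only row. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log(rr_range[0]), np.log(rr_range[1])
    rows = []
    for gender in GENDERS:
        for site in sites:
            if site not in sites_for_gender(gender):
                continue
            log_rr = rng.uniform(lo, hi)
            rr = float(np.exp(log_rr))
            rows.append(
                {
                    "site": site,
                    "gender": gender,
                    "rr": rr,
                    "ci_low": float(np.exp(log_rr - ci_relative_width)),
                    "ci_high": float(np.exp(log_rr + ci_relative_width)),
                }
            )
    return RelativeRiskTable(pd.DataFrame(rows))
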