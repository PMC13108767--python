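"""Two-way fixed-effects linear regression of smoking prevalence on policy exposures.

The estimator is ordinary least squares on a design augmented with country and
year indicator columns (reference-cell coding, first country/year as reference).
At this panel size (~96 rows per gender) the dummy-variable route is exact,
transparent, and numerically identical in its slope coefficients to the
within-transformation. Coefficients are absolute percentage-point changes in
prevalence per unit of the predictor; models are fitted separately per gender
and are never population-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import POLICIES
from .errors import RankError, SingularityError
from .panel import PolicyPanel

INTERACTION_TERM = "mpower:literacy"


def _design_frame(df: pd.DataFrame, predictors: Sequence[str], interaction: bool) -> pd.DataFrame:
    """Listwise-complete rows with the interaction column appended if requested."""
    cols = ["country", "year", "prevalence", *predictors]
    out = df.loc[:, cols].dropna().copy()
    if interaction:
        if not {"mpower", "literacy"} <= set(predictors):
            raise ValueError("interaction model requires both mpower and literacy")
        out[INTERACTION_TERM] = out["mpower"] * out["literacy"]  # uncentered product
    return out


def compute_vif(df: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k), where R^2_k is from
    regressing predictor k on the other predictors (with intercept) over the
    same rows used for fitting. Perfect collinearity yields ``inf``, not an
    exception."""
    if len(predictors) < 2:
        raise ValueError("VIF requires at least 2 predictors")
    X = df.loc[:, list(predictors)].dropna().to_numpy(dtype=float)
    out = {}
    for k, name in enumerate(predictors):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = np.sum((y - y.mean()) ** 2)
        if tss <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def r_squared_components(
    response: pd.Series, fitted: pd.Series, countries: pd.Series
) -> tuple[float, float, float]:
    """Panel fit decomposition as (within, between, overall) squared correlations.

    within: corr^2 of country-demeaned fitted vs country-demeaned response;
    between: corr^2 of country means; overall: corr^2 of raw series.
    A degenerate (zero-variance) component yields ``nan``.
    """

    def _corr2(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) <= 1e-14 or np.std(b) <= 1e-14:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    y = response.to_numpy(dtype=float)
    yhat = fitted.to_numpy(dtype=float)
    grp = pd.DataFrame({"y": y, "yhat": yhat, "country": countries.to_numpy()})
    demeaned = grp[["y", "yhat"]] - grp.groupby("country")[["y", "yhat"]].transform("mean")
    means = grp.groupby("country")[["y", "yhat"]].mean()
    within = _corr2(demeaned["y"].to_numpy(), demeaned["yhat"].to_numpy())
    between = _corr2(means["y"].to_numpy(), means["yhat"].to_numpy())
    overall = _corr2(y, yhat)
    return within, between, overall


@dataclass
class FixedEffectsPanelResults:
    """Fit results of one gender-specific two-way fixed-effects regression."""

    gender: str
    predictors: tuple[str, ...]
    params: pd.Series          # const + predictor slopes (+ interaction)
    bse: pd.Series
    country_effects: pd.Series  # reference country = 0
    year_effects: pd.Series     # reference year = 0
    residuals: pd.Series
    fittedvalues: pd.Series
    r2_within: float
    r2_between: float
    r2_overall: float
    nobs: int
    vif: pd.Series | None = None
    sample: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def beta0(self) -> float:
        return float(self.params["const"])

    @property
    def betas(self) -> pd.Series:
        """Slope coefficients only (percentage points per predictor unit)."""
        return self.params.drop("const")

    def summary(self) -> str:
        lines = [
            f"Two-way fixed-effects OLS — gender: {self.gender}, nobs: {self.nobs}",
            f"predictors: {', '.join(self.predictors)}",
            f"{'term':<20}{'coef':>12}{'se':>12}" + ("" if self.vif is None else f"{'vif':>10}"),
        ]
        for term in self.params.index:
            vif_txt = ""
            if self.vif is not None and term in self.vif.index:
                vif_txt = f"{self.vif[term]:>10.3f}"
            lines.append(f"{term:<20}{self.params[term]:>12.5f}{self.bse[term]:>12.5f}{vif_txt}")
        lines.append(
            f"R² within: {self.r2_within:.4f}  between: {self.r2_between:.4f}  "
            f"overall: {self.r2_overall:.4f}"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One row per coefficient, mirroring the published coefficient-table layout."""
        df = pd.DataFrame({"coef": self.params, "se": self.bse})
        df["gender"] = self.gender
        df["r2_within"] = self.r2_within
        df["r2_between"] = self.r2_between
        df["r2_overall"] = self.r2_overall
        if self.vif is not None:
            df["vif"] = self.vif.reindex(df.index)
        return df.reset_index(names="term")


class FixedEffectsPanelModel:
    """OLS with country and year fixed effects for one gender's policy panel.

    Parameters
    ----------
    data
        Long-format rows with columns ``country, year, prevalence`` and the
        requested predictors. Rows with any missing value among the model's
        variables are dropped listwise (no imputation).
    predictors
        Ordered subset of ``("mpower", "affordability", "literacy")``.
    interaction
        Append the uncentered ``mpower x literacy`` product term.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: Sequence[str],
        gender: str = "",
        interaction: bool = False,
    ):
        bad = [p for p in predictors if p not in POLICIES]
        if bad:
            raise ValueError(f"unknown predictor(s) {bad}; choose from {POLICIES}")
        self.predictors = tuple(predictors)
        self.gender = gender
        self.interaction = interaction
        self.data = _design_frame(data, self.predictors, interaction)

    @classmethod
    def from_panel(
        cls,
        panel: PolicyPanel,
        gender: str,
        predictors: Sequence[str],
        interaction: bool = False,
    ) -> "FixedEffectsPanelModel":
        """Build from a :class:`PolicyPanel`, restricted to its fitting years."""
        return cls(panel.fitting_frame(gender), predictors, gender=gender,
                   interaction=interaction)

    def fit(self) -> FixedEffectsPanelResults:
        df = self.data
        terms = list(self.predictors) + ([INTERACTION_TERM] if self.interaction else [])
        n_countries = df["country"].nunique()
        n_years = df["year"].nunique()
        if n_countries < 2 or n_years < 2:
            raise RankError(
                f"fixed-effects fit needs >= 2 countries and >= 2 years after "
                f"dropping incomplete rows (got {n_countries} countries, {n_years} years)"
            )

        # A predictor without within-country variation is absorbed by the
        # country dummies: refuse rather than return an arbitrary solution.
        for p in self.predictors:
            within = df[p] - df.groupby("country")[p].transform("mean")
            if float(np.abs(within).max()) < 1e-10:
                raise SingularityError(
                    f"predictor {p!r} has zero within-country variance; "
                    "it is collinear with the country fixed effects"
                )

        countries = sorted(df["country"].unique())
        years = sorted(df["year"].unique())
        c_dum = pd.get_dummies(
            pd.Categorical(df["country"], categories=countries), prefix="country",
            drop_first=True, dtype=float)
        y_dum = pd.get_dummies(
            pd.Categorical(df["year"], categories=years), prefix="year",
            drop_first=True, dtype=float)
        X = pd.concat(
            [df.loc[:, terms].astype(float).reset_index(drop=True),
             c_dum.reset_index(drop=True), y_dum.reset_index(drop=True)],
            axis=1,
        )
        X.insert(0, "const", 1.0)
        y = df["prevalence"].astype(float).reset_index(drop=True)
        if len(y) <= X.shape[1]:
            raise RankError(
                f"{len(y)} observations for {X.shape[1]} parameters; "
                "the model is not identified"
            )

        ols = sm.OLS(y, X).fit()

        params = ols.params[["const", *terms]]
        bse = ols.bse[["const", *terms]]
        country_effects = pd.Series(
            {countries[0]: 0.0}
            | {c: float(ols.params[f"country_{c}"]) for c in countries[1:]},
            name="country_effect",
        )
        year_effects = pd.Series(
            {years[0]: 0.0} | {t: float(ols.params[f"year_{t}"]) for t in years[1:]},
            name="year_effect",
        )
        fitted = pd.Series(ols.fittedvalues.to_numpy(), index=df.index, name="fitted")
        resid = pd.Series(ols.resid.to_numpy(), index=df.index, name="resid")
        r2w, r2b, r2o = r_squared_components(df["prevalence"], fitted, df["country"])
        vif = compute_vif(df, terms) if len(terms) >= 2 else None

        return FixedEffectsPanelResults(
            gender=self.gender,
            predictors=tuple(terms),
            params=params,
            bse=bse,
            country_effects=country_effects,
            year_effects=year_effects,
            residuals=resid,
            fittedvalues=fitted,
            r2_within=r2w,
            r2_between=r2b,
            r2_overall=r2o,
            nobs=len(y),
            vif=vif,
            sample=df,
        )


def fit_fixed_effects(
    panel: PolicyPanel,
    gender: str,
    predictors: Sequence[str],
    interaction: bool = False,
) -> FixedEffectsPanelResults:
    """Convenience wrapper: build the model from a panel and fit it."""
    return FixedEffectsPanelModel.from_panel(panel, gender, predictors, interaction).fit()


MODEL_SPECS: dict[str, dict] = {
    "m1": {"predictors": ("mpower",), "interaction": False},
    "m2": {"predictors": ("affordability",), "interaction": False},
    "m3": {"predictors": ("literacy",), "interaction": False},
    "m4": {"predictors": ("mpower", "affordability", "literacy"), "interaction": False},
    "m4x": {"predictors": ("mpower", "affordability", "literacy"), "interaction": True},
}


def fit_all_models(panel: PolicyPanel, gender: str,
                   models: Sequence[str] = ("m1", "m2", "m3", "m4")) -> dict[str, FixedEffectsPanelResults]:
    """Fit the univariable (m1-m3), multivariable (m4), and optionally
    interaction (m4x) specifications for one gender."""
    out = {}
    for name in models:
        spec = MODEL_SPECS[name]
        out[name] = fit_fixed_effects(panel, gender, spec["predictors"], spec["interaction"])
    return out
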