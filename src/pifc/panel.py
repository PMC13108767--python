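"""Country-level policy panel, incidence anchors, relative-risk table, and HDI map.

All tabular I/O is comma-delimited UTF-8 with a mandatory header row and period
decimal separator. Prevalence and literacy are stored as percent (0-100)
throughout; conversion to proportion happens only inside Levin's formula
(:mod:`pifc.attribution`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    ANALYSIS_COUNTRIES,
    ANCHOR_YEARS,
    BASELINE_YEAR,
    FIT_YEARS,
    GENDERS,
    HDI_GROUPS,
    MPOWER_MAX,
    MPOWER_MIN,
    SITES,
    WOMEN_ONLY_SITES,
    canonical_country,
)
from .errors import (
    CompletenessError,
    SchemaError,
    UniquenessError,
    ValidationError,
)

PANEL_COLUMNS = ("country", "year", "gender", "prevalence", "mpower", "affordability", "literacy")
ANCHOR_COLUMNS = ("country", "gender", "site", "year", "cases")
RR_COLUMNS = ("site", "gender", "rr")


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


@dataclass
class PolicyPanel:
    """Long-format records of smoking prevalence and the three policy exposures.

    Parameters
    ----------
    data
        One row per (country, year, gender) with columns
        ``country, year, gender, prevalence, mpower, affordability, literacy``.
        Prevalence and literacy in percent; mpower on the 7-34 composite scale;
        affordability as percent of GDP per capita for 100 cigarette packs.
    fit_years
        Calendar years used for regression fitting (baseline rows, e.g. 2025,
        sit in the panel but outside ``fit_years``).
    """

    data: pd.DataFrame
    fit_years: tuple[int, ...] = FIT_YEARS

    def __post_init__(self) -> None:
        self.data = validate_panel_frame(self.data)
        self.fit_years = tuple(int(y) for y in self.fit_years)

    # -- views ---------------------------------------------------------------
    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["country"].unique()))

    def gender_subset(self, gender: str) -> pd.DataFrame:
        """Rows for one gender; men/women subsets partition the panel."""
        if gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {gender!r}")
        return self.data[self.data["gender"] == gender].copy()

    def fitting_frame(self, gender: str) -> pd.DataFrame:
        sub = self.gender_subset(gender)
        return sub[sub["year"].isin(self.fit_years)].copy()

    def baseline(self, year: int = BASELINE_YEAR) -> pd.DataFrame:
        """The (country, gender) baseline records for `year` (default 2025)."""
        return self.data[self.data["year"] == year].copy()

    def latest_policy_values(self, prefer_year: int = BASELINE_YEAR) -> pd.DataFrame:
        """Policy values per (country, gender) from `prefer_year` when present,
        else the latest observed year; records the source year per row."""
        out = []
        for (country, gender), grp in self.data.groupby(["country", "gender"], sort=True):
            at = grp[grp["year"] == prefer_year]
            row = at.iloc[0] if len(at) else grp.sort_values("year").iloc[-1]
            out.append(
                {
                    "country": country,
                    "gender": gender,
                    "mpower": row["mpower"],
                    "affordability": row["affordability"],
                    "literacy": row["literacy"],
                    "policy_source_year": int(row["year"]),
                }
            )
        return pd.DataFrame(out)

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        # repr-precision float text so a write/read round trip is bit exact
        self.data.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, schema: Mapping[str, str] | None = None,
                 fit_years: tuple[int, ...] = FIT_YEARS) -> "PolicyPanel":
        return load_policy_panel(path, schema=schema, fit_years=fit_years)

    def __len__(self) -> int:
        return len(self.data)


def validate_panel_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a raw panel frame; raises with row diagnostics."""
    _require_columns(df, PANEL_COLUMNS, "panel")
    df = df.loc[:, list(PANEL_COLUMNS)].copy()
    df["country"] = df["country"].map(canonical_country)
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()
    df["year"] = df["year"].astype(int)
    for col in ("prevalence", "mpower", "affordability", "literacy"):
        # float64 throughout so CSV round trips are dtype-stable
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    problems: list[str] = []

    def _flag(mask: pd.Series, message: str) -> None:
        for _, row in df.loc[mask].iterrows():
            key = (row["country"], int(row["year"]), row["gender"])
            problems.append(f"{key}: {message.format(**row)}")

    _flag(~df["gender"].isin(GENDERS), "gender must be men/women")
    _flag(df["prevalence"].notna() & ~df["prevalence"].between(0.0, 100.0),
          "prevalence {prevalence} outside [0, 100]")
    _flag(df["mpower"].notna() & ~df["mpower"].between(MPOWER_MIN, MPOWER_MAX),
          f"mpower {{mpower}} outside [{MPOWER_MIN}, {MPOWER_MAX}]")
    _flag(df["literacy"].notna() & ~df["literacy"].between(0.0, 100.0),
          "literacy {literacy} outside [0, 100]")
    _flag(df["affordability"].notna() & (df["affordability"] < 0),
          "affordability {affordability} negative")
    if problems:
        raise ValidationError("panel rows violate field invariants", problems)

    dup = df.duplicated(subset=["country", "year", "gender"])
    if dup.any():
        keys = df.loc[dup, ["country", "year", "gender"]].apply(tuple, axis=1).tolist()
        raise UniquenessError(f"duplicate (country, year, gender) keys: {keys}")
    return df.reset_index(drop=True)


def load_policy_panel(path: str | Path, schema: Mapping[str, str] | None = None,
                      fit_years: tuple[int, ...] = FIT_YEARS) -> PolicyPanel:
    """Read a policy panel CSV.

    ``schema`` maps file column names to the canonical names, e.g.
    ``{"Country": "country", "Smoking %": "prevalence"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    return PolicyPanel(df, fit_years=fit_years)


# ---------------------------------------------------------------------------
# Incidence anchors
# ---------------------------------------------------------------------------

def validate_anchor_frame(df: pd.DataFrame,
                          anchor_years: tuple[int, ...] = ANCHOR_YEARS) -> pd.DataFrame:
    """Validate projected-case anchors: non-negative counts, cervix women-only,
    and a complete six-year grid per (country, gender, site) stratum."""
    _require_columns(df, ANCHOR_COLUMNS, "anchors")
    df = df.loc[:, list(ANCHOR_COLUMNS)].copy()
    df["country"] = df["country"].map(canonical_country)
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()
    df["site"] = df["site"].astype(str).str.strip().str.lower()
    df["year"] = df["year"].astype(int)
    df["cases"] = pd.to_numeric(df["cases"], errors="coerce").astype(float)

    problems: list[str] = []

    def _flag(mask: pd.Series, message: str) -> None:
        for _, row in df.loc[mask].iterrows():
            key = (row["country"], row["gender"], row["site"], int(row["year"]))
            problems.append(f"{key}: {message}")

    _flag(~df["gender"].isin(GENDERS), "gender must be men/women")
    _flag(~df["site"].isin(SITES), "unknown cancer site")
    _flag(df["site"].isin(WOMEN_ONLY_SITES) & (df["gender"] == "men"),
          "women-only site cannot have gender=men")
    _flag(df["cases"].isna() | (df["cases"] < 0),
          "cases must be a non-negative number")
    _flag(~df["year"].isin(anchor_years), f"year not an anchor year {anchor_years}")
    if problems:
        raise ValidationError("anchor rows violate field invariants", problems)

    dup = df.duplicated(subset=["country", "gender", "site", "year"])
    if dup.any():
        keys = df.loc[dup, ["country", "gender", "site", "year"]].apply(tuple, axis=1).tolist()
        raise UniquenessError(f"duplicate anchor keys: {keys}")

    missing: list[str] = []
    for (country, gender, site), grp in df.groupby(["country", "gender", "site"], sort=True):
        got = set(grp["year"])
        lack = [y for y in anchor_years if y not in got]
        if lack:
            missing.append(f"({country}, {gender}, {site}) missing year(s) {lack}")
    if missing:
        raise CompletenessError("anchor grid incomplete", missing)
    return df.reset_index(drop=True)


def load_incidence_anchors(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_anchor_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Relative risks
# ---------------------------------------------------------------------------

@dataclass
class RelativeRiskTable:
    """Site- and gender-specific relative risks of cancer for current smoking.

    ``lookup(site, gender)`` returns the RR row, falling back to a
    gender="both" row when no gender-specific value exists (the fallback is
    recorded in :attr:`fallbacks`). For inapplicable strata (cervix, men) it
    returns ``None`` so aggregation loops can skip rather than catch.
    """

    data: pd.DataFrame
    fallbacks: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = validate_rr_frame(self.data)

    def lookup(self, site: str, gender: str) -> pd.Series | None:
        if site in WOMEN_ONLY_SITES and gender == "men":
            return None  # not applicable, by construction
        hit = self.data[(self.data["site"] == site) & (self.data["gender"] == gender)]
        if len(hit):
            return hit.iloc[0]
        both = self.data[(self.data["site"] == site) & (self.data["gender"] == "both")]
        if len(both):
            self.fallbacks.append((site, gender))
            return both.iloc[0]
        return None

    def gender_expanded(self) -> pd.DataFrame:
        """One row per applicable (site, gender) pair, resolving 'both' rows."""
        rows = []
        for gender in GENDERS:
            for site in SITES:
                hit = self.lookup(site, gender)
                if hit is not None:
                    rows.append({"site": site, "gender": gender, "rr": hit["rr"],
                                 "ci_low": hit.get("ci_low", np.nan),
                                 "ci_high": hit.get("ci_high", np.nan)})
        return pd.DataFrame(rows)


def validate_rr_frame(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, RR_COLUMNS, "relative-risk")
    keep = [c for c in ("site", "gender", "rr", "ci_low", "ci_high") if c in df.columns]
    df = df.loc[:, keep].copy()
    df["site"] = df["site"].astype(str).str.strip().str.lower()
    df["gender"] = df["gender"].astype(str).str.strip().str.lower()
    df["rr"] = pd.to_numeric(df["rr"], errors="coerce")
    for c in ("ci_low", "ci_high"):
        if c not in df.columns:
            df[c] = np.nan
        else:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    problems: list[str] = []
    for _, row in df.iterrows():
        key = (row["site"], row["gender"])
        if row["site"] not in SITES:
            problems.append(f"{key}: unknown site")
        if row["gender"] not in GENDERS + ("both",):
            problems.append(f"{key}: gender must be men/women/both")
        if pd.isna(row["rr"]) or row["rr"] <= 0:
            problems.append(f"{key}: rr must be > 0")
        if pd.notna(row["ci_low"]) and pd.notna(row["ci_high"]):
            if not (row["ci_low"] <= row["rr"] <= row["ci_high"]):
                problems.append(f"{key}: rr outside its own CI")
    if problems:
        raise ValidationError("relative-risk rows violate field invariants", problems)

    dup = df.duplicated(subset=["site", "gender"])
    if dup.any():
        keys = df.loc[dup, ["site", "gender"]].apply(tuple, axis=1).tolist()
        raise UniquenessError(f"duplicate (site, gender) RR rows: {keys}")
    return df.reset_index(drop=True)


def load_rr_table(path: str | Path) -> RelativeRiskTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return RelativeRiskTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# HDI grouping
# ---------------------------------------------------------------------------

def default_hdi_map() -> dict[str, str]:
    """The canonical 16-country HDI grouping (low/medium/high)."""
    return dict(HDI_GROUPS)


def load_hdi_map(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, ("country", "hdi_group"), "hdi")
    df["country"] = df["country"].map(canonical_country)
    df["hdi_group"] = df["hdi_group"].astype(str).str.strip().str.lower()
    bad = sorted(set(df["hdi_group"]) - {"low", "medium", "high"})
    if bad:
        raise ValidationError("hdi_group must be low/medium/high", bad)
    dup = df.duplicated(subset=["country"])
    if dup.any():
        raise UniquenessError(f"duplicate countries in HDI map: {df.loc[dup, 'country'].tolist()}")
    return dict(zip(df["country"], df["hdi_group"]))


def check_hdi_coverage(hdi: Mapping[str, str], countries: Iterable[str]) -> None:
    missing = sorted(set(countries) - set(hdi))
    if missing:
        raise CompletenessError("HDI map does not cover all analysis countries", missing)
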