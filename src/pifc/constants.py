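"""Region definitions, cancer-site list, scenario names, and canonical country keys.

The analysis covers the 16 WHO Eastern Mediterranean Region (EMR) countries with
recent smoking-prevalence data. Five EMR members (Sudan, Somalia, Libya, Syria,
Djibouti) are excluded from the canonical set but the loaders accept any country
set; the analysis configuration pins these 16.
"""

from __future__ import annotations

# Canonical analysis countries, grouped by Human Development Index tier.
HDI_LOW = ("Afghanistan", "Pakistan", "Iraq", "Morocco", "Yemen")
HDI_MEDIUM = ("Egypt", "Iran", "Lebanon", "Tunisia", "Jordan")
HDI_HIGH = ("Bahrain", "Kuwait", "Oman", "Qatar", "Saudi Arabia", "UAE")

ANALYSIS_COUNTRIES = HDI_LOW + HDI_MEDIUM + HDI_HIGH

HDI_GROUPS: dict[str, str] = (
    {c: "low" for c in HDI_LOW}
    | {c: "medium" for c in HDI_MEDIUM}
    | {c: "high" for c in HDI_HIGH}
)

# Name variants seen across data sources and figure captions -> canonical key.
_COUNTRY_ALIASES: dict[str, str] = {
    "united arab emirates": "UAE",
    "uae": "UAE",
    "islamic republic of iran": "Iran",
    "iran (islamic republic of)": "Iran",
    "iran": "Iran",
    "kingdom of saudi arabia": "Saudi Arabia",
    "saudi arabia": "Saudi Arabia",
    "ksa": "Saudi Arabia",
    "occupied palestinian territory": "Palestine",
    "palestine": "Palestine",
}


def canonical_country(name: str) -> str:
    """Map a country-name variant to its canonical key.

    Unknown names are returned stripped but otherwise untouched, so the
    loaders accept arbitrary country sets (synthetic panels, subsets).
    """
    key = str(name).strip()
    return _COUNTRY_ALIASES.get(key.lower(), key)


# The 13 cancer sites causally linked to tobacco smoking (IARC monographs).
SITES = (
    "lung",
    "larynx",
    "pharynx",
    "esophagus",
    "oral cavity",
    "bladder",
    "leukemia",
    "stomach",
    "colorectal",
    "cervix",
    "pancreas",
    "liver",
    "kidney",
)

# Sites applicable per gender: cervix exists only for women.
WOMEN_ONLY_SITES = ("cervix",)

GENDERS = ("men", "women")

def sites_for_gender(gender: str) -> tuple[str, ...]:
    if gender == "women":
        return SITES
    return tuple(s for s in SITES if s not in WOMEN_ONLY_SITES)


# Policy predictors and their scenario targets.
POLICIES = ("mpower", "affordability", "literacy")
MPOWER_MIN, MPOWER_MAX = 7, 34
LITERACY_MAX = 100.0
AFFORDABILITY_STEP = 10.0  # scenario: a 10-unit increase regardless of current value

SCENARIOS = ("baseline", "max_mpower", "affordability_plus10", "max_literacy", "combined")
SINGLE_POLICY_SCENARIOS: dict[str, str] = {
    "max_mpower": "mpower",
    "affordability_plus10": "affordability",
    "max_literacy": "literacy",
}

# Projection window and anchor grid.
ANCHOR_YEARS = (2025, 2030, 2035, 2040, 2045, 2050)
PROJECTION_START, PROJECTION_END = 2025, 2050
FIT_YEARS = (2010, 2012, 2014, 2016, 2018, 2020)
BASELINE_YEAR = 2025
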