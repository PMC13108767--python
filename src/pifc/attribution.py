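"""Levin attributable fractions, potential impact fractions, and case counts.

The population attributable fraction for prevalence *p* (proportion) and
relative risk *RR* is Levin's formula

    PAF = p (RR - 1) / (1 + p (RR - 1)),

the share of cases that would not occur absent the exposure. The potential
impact fraction of a policy scenario is PIF = PAF(current) - PAF(scenario),
and preventable cases = PIF x projected cases. PAFs are always computed at
the finest (country, gender, site, scenario) stratum; because Levin's formula
is nonlinear, coarser levels are obtained only by case-weighting
(aggregate PAF = sum attributable / sum total), never by averaging fractions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import WOMEN_ONLY_SITES
from .errors import CompletenessError, DomainError, UniquenessError
from .panel import RelativeRiskTable

STRATUM_KEYS = ("country", "gender", "site", "scenario")
COUNT_COLUMNS = ("total_cases", "attributable_cases", "preventable_cases")


def levin_paf(p, rr):
    """Levin's attributable fraction for exposure prevalence ``p`` (a
    proportion in [0, 1], *not* percent) and relative risk ``rr`` > 0.

    Accepts scalars or arrays. Raises :class:`DomainError` when ``p`` is
    outside [0, 1] — the guard that catches percent/proportion confusion.
    """
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError(
            "prevalence must be a proportion in [0, 1]; got values outside "
            "that range (were percent values passed?)")
    if np.any(rr <= 0):
        raise DomainError("relative risk must be > 0")
    excess = p * (rr - 1.0)
    out = excess / (1.0 + excess)
    return float(out) if out.ndim == 0 else out


def attribution_table(
    scenario_prevalence: pd.DataFrame,
    rr: RelativeRiskTable,
    cumulative: pd.DataFrame,
) -> pd.DataFrame:
    """Stratum-level attribution: one row per (country, gender, site, scenario).

    Parameters
    ----------
    scenario_prevalence
        Output of :func:`pifc.scenarios.build_scenario_table` (percent scale).
    rr
        Relative-risk table; (cervix, men) is inapplicable and skipped.
    cumulative
        Per-stratum projected totals from :func:`pifc.incidence.cumulative_cases`.

    Returns
    -------
    Frame with columns ``country, gender, site, scenario, rr, paf_current,
    paf_scenario, pif, total_cases, attributable_cases, preventable_cases``.
    """
    rr_rows = rr.gender_expanded()
    merged = cumulative.merge(rr_rows[["site", "gender", "rr"]],
                              on=["site", "gender"], how="left")
    applicable = ~((merged["site"].isin(WOMEN_ONLY_SITES)) & (merged["gender"] == "men"))
    missing = merged[applicable & merged["rr"].isna()]
    if len(missing):
        strata = missing[["site", "gender"]].drop_duplicates().apply(tuple, axis=1).tolist()
        raise CompletenessError("no relative risk for applicable strata", strata)
    merged = merged[applicable & merged["rr"].notna()]

    out = merged.merge(
        scenario_prevalence[["country", "gender", "scenario",
                             "baseline_prevalence", "prevalence"]],
        on=["country", "gender"], how="inner")
    out["paf_current"] = levin_paf(out["baseline_prevalence"] / 100.0, out["rr"])
    out["paf_scenario"] = levin_paf(out["prevalence"] / 100.0, out["rr"])
    out["pif"] = out["paf_current"] - out["paf_scenario"]
    out["attributable_cases"] = out["paf_current"] * out["total_cases"]
    out["preventable_cases"] = out["pif"] * out["total_cases"]
    cols = ["country", "gender", "site", "scenario", "rr", "paf_current",
            "paf_scenario", "pif", "total_cases", "attributable_cases",
            "preventable_cases"]
    return out[cols].sort_values(["country", "gender", "site", "scenario"]).reset_index(drop=True)


def stratum_attribution(
    baseline_prevalence_percent: float,
    scenario_prevalence_percent: float,
    rr: float,
    total_cases: float,
) -> dict[str, float]:
    """Attribution arithmetic for a single stratum (scalar convenience API)."""
    paf_cur = levin_paf(baseline_prevalence_percent / 100.0, rr)
    paf_scen = levin_paf(scenario_prevalence_percent / 100.0, rr)
    pif = paf_cur - paf_scen
    return {
        "paf_current": paf_cur,
        "paf_scenario": paf_scen,
        "pif": pif,
        "total_cases": total_cases,
        "attributable_cases": paf_cur * total_cases,
        "preventable_cases": pif * total_cases,
    }


def aggregate(
    strata: pd.DataFrame,
    by: Sequence[str],
    hdi: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Case-weighted aggregation of stratum attribution results.

    ``by`` may contain any of ``country, gender, site, scenario, hdi_group,
    region``; ``scenario`` is always kept as a grouping key. Counts sum;
    aggregate PAF = sum(attributable)/sum(total); aggregate PIF =
    sum(preventable)/sum(total). Requires the input strata to be unique on
    (country, gender, site, scenario) — duplicated strata would double-count.
    """
    df = strata.copy()
    dup = df.duplicated(subset=list(STRATUM_KEYS))
    if dup.any():
        keys = df.loc[dup, list(STRATUM_KEYS)].apply(tuple, axis=1).tolist()
        raise UniquenessError(f"overlapping strata would double-count: {keys[:5]}")

    by = list(dict.fromkeys([*by, "scenario"]))  # scenario always retained
    if "hdi_group" in by:
        if hdi is None:
            raise ValueError("aggregating by hdi_group requires an HDI map")
        unmapped = sorted(set(df["country"]) - set(hdi))
        if unmapped:
            raise CompletenessError("countries missing from HDI map", unmapped)
        df["hdi_group"] = df["country"].map(hdi)
    if "region" in by:
        df["region"] = "EMR"

    grouped = df.groupby(by, sort=True)[list(COUNT_COLUMNS)].sum().reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["paf_current"] = grouped["attributable_cases"] / grouped["total_cases"]
        grouped["pif"] = grouped["preventable_cases"] / grouped["total_cases"]
    return grouped
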