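"""Annual cancer-incidence series from 5-year projection anchors.

Projected case counts arrive at 5-year intervals (2025, 2030, ..., 2050). The
annual series takes the difference between consecutive anchors, divides it by
five, and applies that constant increment within the interval — piecewise
linear interpolation that reproduces every anchor exactly. Cumulative totals
sum calendar years 2025 through 2050 inclusive (26 annual values); pass an
explicit ``year_to=2049`` to reproduce a 25-value convention. Fractional case
counts are carried unrounded through all arithmetic; rounding happens only at
report time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import ANCHOR_YEARS, PROJECTION_END, PROJECTION_START
from .errors import CompletenessError


def annualize(anchors: pd.DataFrame,
              anchor_years: tuple[int, ...] = ANCHOR_YEARS) -> pd.DataFrame:
    """Interpolate anchors to an annual long-format series.

    Parameters
    ----------
    anchors
        Validated frame with columns ``country, gender, site, year, cases``
        and all anchor years present per stratum.

    Returns
    -------
    Long frame ``country, gender, site, year, cases`` for every calendar year
    from the first to the last anchor year.
    """
    years_all = np.arange(min(anchor_years), max(anchor_years) + 1)
    frames = []
    for (country, gender, site), grp in anchors.groupby(
            ["country", "gender", "site"], sort=True):
        got = grp.sort_values("year")
        lack = [y for y in anchor_years if y not in set(got["year"])]
        if lack:
            raise CompletenessError(
                f"stratum ({country}, {gender}, {site}) missing anchor year(s)", lack)
        cases = np.interp(years_all, got["year"].to_numpy(dtype=float),
                          got["cases"].to_numpy(dtype=float))
        frames.append(pd.DataFrame({
            "country": country, "gender": gender, "site": site,
            "year": years_all, "cases": cases,
        }))
    return pd.concat(frames, ignore_index=True)


def cumulative_cases(series: pd.DataFrame,
                     year_from: int = PROJECTION_START,
                     year_to: int = PROJECTION_END) -> pd.DataFrame:
    """Inclusive sum of annual cases over [year_from, year_to] per stratum.

    Returns one row per (country, gender, site) with column ``total_cases``.
    """
    if year_from > year_to:
        raise ValueError("year_from must be <= year_to")
    have = series["year"]
    if year_from < have.min() or year_to > have.max():
        raise ValueError(
            f"requested range [{year_from}, {year_to}] outside the annualized "
            f"series [{have.min()}, {have.max()}]")
    window = series[(series["year"] >= year_from) & (series["year"] <= year_to)]
    out = (window.groupby(["country", "gender", "site"], sort=True)["cases"]
           .sum().rename("total_cases").reset_index())
    return out
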