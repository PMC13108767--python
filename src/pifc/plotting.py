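"""Bar-plot export of potential impact fractions with CI whiskers."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_LEVEL_KEYS = {"country_pif": "country", "site_pif": "site", "hdi_pif": "hdi_group"}


def plot_pif_bars(table: pd.DataFrame, key: str, ax=None):
    """Grouped bars of PIF (%) per `key` value and scenario; CI whiskers when
    ``pif_ci_low/high`` columns are present, otherwise a warning and plain bars."""
    df = table[table["scenario"] != "baseline"].copy()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.55 * df[key].nunique() + 2), 4))
    scenarios = sorted(df["scenario"].unique())
    groups = sorted(df[key].unique())
    width = 0.8 / len(scenarios)
    has_ci = {"pif_ci_low", "pif_ci_high"} <= set(df.columns)
    if not has_ci:
        warnings.warn("no CI columns in table; plotting bars without whiskers",
                      stacklevel=2)
    for si, scenario in enumerate(scenarios):
        sub = df[df["scenario"] == scenario].set_index(key).reindex(groups)
        x = [gi + si * width for gi in range(len(groups))]
        y = 100.0 * sub["pif"]
        yerr = None
        if has_ci:
            lo = 100.0 * (sub["pif"] - sub["pif_ci_low"])
            hi = 100.0 * (sub["pif_ci_high"] - sub["pif"])
            yerr = [lo.clip(lower=0), hi.clip(lower=0)]
        ax.bar(x, y, width=width, label=scenario, yerr=yerr, capsize=2)
    ax.set_xticks([gi + 0.4 - width / 2 for gi in range(len(groups))])
    ax.set_xticklabels(groups, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("preventable share of projected cases (PIF, %)")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax


def render_summary_plots(tables: Mapping[str, pd.DataFrame],
                         out_dir: str | Path) -> list[Path]:
    """One PIF bar plot per available grouping (country, site, HDI tier)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, key in _LEVEL_KEYS.items():
        if name not in tables:
            continue
        ax = plot_pif_bars(tables[name], key)
        path = out_dir / f"{name}.png"
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
        written.append(path)
    return written
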