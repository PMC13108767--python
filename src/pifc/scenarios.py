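"""Counterfactual 2025 smoking prevalence under tobacco-control policy scenarios.

Four alternative scenarios against the 2025 baseline: full MPOWER
implementation (score -> 34), a 10-unit increase in the cigarette
affordability index, maximal adult literacy (-> 100 %), and all three
combined. Each policy's prevalence reduction is (policy gap) x (fitted
regression coefficient), applied as a one-time level shift to the 2025
baseline and held constant through 2050. Single-policy scenarios use the
matching univariable-model coefficient; the combined scenario uses the
multivariable-model coefficients and sums the three reductions.
Counterfactual prevalence is floored at zero (and symmetrically capped at
100 for pathological positive-coefficient inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    AFFORDABILITY_STEP,
    BASELINE_YEAR,
    LITERACY_MAX,
    MPOWER_MAX,
    POLICIES,
    SCENARIOS,
    SINGLE_POLICY_SCENARIOS,
)
from .errors import ConfigurationError, ValidationError
from .panel import PolicyPanel
from .regression import FixedEffectsPanelResults

SCENARIO_POLICIES: dict[str, tuple[str, ...]] = {
    "baseline": (),
    "max_mpower": ("mpower",),
    "affordability_plus10": ("affordability",),
    "max_literacy": ("literacy",),
    "combined": POLICIES,
}


def policy_gap(current: Mapping[str, float], policy: str) -> float:
    """Distance from a country's current policy value to its scenario target.

    mpower: 34 - current; literacy: 100 - current; affordability: a flat
    10-unit increase regardless of the current value.
    """
    if policy == "mpower":
        value = float(current["mpower"])
        if value > MPOWER_MAX:
            raise ValidationError(f"mpower {value} exceeds the maximum score {MPOWER_MAX}")
        return MPOWER_MAX - value
    if policy == "literacy":
        value = float(current["literacy"])
        if value > LITERACY_MAX:
            raise ValidationError(f"literacy {value} exceeds 100%")
        return LITERACY_MAX - value
    if policy == "affordability":
        return AFFORDABILITY_STEP
    raise ValueError(f"unknown policy {policy!r}")


@dataclass
class ScenarioCoefficients:
    """Per-gender coefficient lookup for the scenario engine.

    ``univariable[policy]`` feeds the single-policy scenarios (each from its
    own one-predictor fixed-effects model); ``multivariable[policy]`` feeds
    the combined scenario (all three policies fitted jointly).
    """

    gender: str
    univariable: dict[str, float]
    multivariable: dict[str, float]

    @classmethod
    def from_fits(cls, fits: Mapping[str, FixedEffectsPanelResults], gender: str
                  ) -> "ScenarioCoefficients":
        """Extract from a ``{"m1": ..., "m2": ..., "m3": ..., "m4": ...}`` dict."""
        for name in ("m1", "m2", "m3", "m4"):
            if name not in fits:
                raise ConfigurationError(f"missing fitted model {name!r} for gender {gender!r}")
        uni = {
            "mpower": float(fits["m1"].params["mpower"]),
            "affordability": float(fits["m2"].params["affordability"]),
            "literacy": float(fits["m3"].params["literacy"]),
        }
        multi = {p: float(fits["m4"].params[p]) for p in POLICIES}
        return cls(gender=gender, univariable=uni, multivariable=multi)

    def for_scenario(self, scenario: str) -> dict[str, float]:
        if scenario == "combined":
            return dict(self.multivariable)
        if scenario in SINGLE_POLICY_SCENARIOS:
            policy = SINGLE_POLICY_SCENARIOS[scenario]
            return {policy: self.univariable[policy]}
        return {}


def project_prevalence(
    baseline_percent: float,
    gaps: Mapping[str, float],
    coefficients: Mapping[str, float],
    scenario: str,
) -> tuple[float, float]:
    """Counterfactual prevalence for one (country, gender) under one scenario.

    reduction = sum over the scenario's policies of (-coefficient x gap); the
    arithmetic is fully signed, so a positive coefficient produces a negative
    reduction (higher counterfactual prevalence). Returns
    ``(reduction, max(0, min(100, baseline - reduction)))``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    reduction = 0.0
    for policy in SCENARIO_POLICIES[scenario]:
        if policy not in coefficients:
            raise ConfigurationError(
                f"scenario {scenario!r} needs a coefficient for {policy!r}"
            )
        if policy not in gaps:
            raise ConfigurationError(f"scenario {scenario!r} needs a gap for {policy!r}")
        reduction += -float(coefficients[policy]) * float(gaps[policy])
    prevalence = float(np.clip(baseline_percent - reduction, 0.0, 100.0))
    return reduction, prevalence


def build_scenario_table(
    panel: PolicyPanel,
    coefficients: Mapping[str, ScenarioCoefficients],
    baseline_year: int = BASELINE_YEAR,
    marginal_coefficients: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Scenario-prevalence table: 5 scenarios x countries x genders.

    Gaps are computed from each (country, gender)'s policy values at
    ``baseline_year`` when present, else the latest observed year; the source
    year is recorded per row. Countries with no baseline prevalence are
    skipped and listed in the frame's ``attrs["skipped"]``.

    ``marginal_coefficients`` optionally overrides the combined-scenario
    coefficients with country-specific marginal effects (used by the
    interaction sensitivity): per gender, a frame indexed by country with one
    column per policy.
    """
    baseline = panel.baseline(baseline_year).set_index(["country", "gender"])
    policy_now = panel.latest_policy_values(prefer_year=baseline_year).set_index(
        ["country", "gender"])
    skipped = []
    rows = []
    for country, gender in sorted(set(map(tuple, panel.data[["country", "gender"]].to_numpy()))):
        if (country, gender) not in baseline.index:
            skipped.append((country, gender))
            continue
        base_prev = float(baseline.loc[(country, gender), "prevalence"])
        now = policy_now.loc[(country, gender)]
        gaps = {p: policy_gap(now, p) for p in POLICIES}
        coeffs = coefficients[gender]
        for scenario in SCENARIOS:
            sc_coeffs = coeffs.for_scenario(scenario)
            source = "univariable" if scenario in SINGLE_POLICY_SCENARIOS else (
                "multivariable" if scenario == "combined" else "none")
            if (scenario == "combined" and marginal_coefficients is not None):
                sc_coeffs = dict(marginal_coefficients[gender].loc[country])
                source = "interaction-marginal"
            reduction, prev = project_prevalence(base_prev, gaps, sc_coeffs, scenario)
            rows.append(
                {
                    "country": country,
                    "gender": gender,
                    "scenario": scenario,
                    "baseline_prevalence": base_prev,
                    "reduction": reduction,
                    "prevalence": prev,
                    "policy_source_year": int(now["policy_source_year"]),
                    "coefficient_source": source,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out
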