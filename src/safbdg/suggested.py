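"""Suggested-cut-point adherence scoring (0 / 0.5 / 1 per guideline).

Nine of the eleven South African food-based dietary guidelines are scorable
from QFFQ-style data (the salt and water guidelines are not). Each
guideline contributes at most one point; the two protein-food
sub-recommendations and the two fats sub-recommendations contribute 0.5
each; the added-sugar guideline has a three-level scoring (<6 %TE -> 1,
6-<10 %TE -> 0.5, otherwise 0). The overall score therefore lies in [0, 9],
and "half adherence" means an overall score strictly above 4.5.

Boundary conventions (ties resolved by the wording of each rule):
"at least"-phrased thresholds are inclusive (>=); "less than"-phrased
thresholds are strict (<); the fat range 20-30 %TE is inclusive on both
ends; the fish/chicken/lean-meat rule requires strictly positive intake
below 90 g/d (pure abstainers do not satisfy "can be eaten daily" —
configurable via ``meat_require_positive``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

#: Guideline identifiers in report order.
GUIDELINES = (
    "variety", "active", "starchy", "fruit_veg", "legumes", "dairy",
    "protein_foods", "fats", "sugar",
)

#: Sub-recommendation component columns (each worth up to 0.5).
SUB_COMPONENTS = ("protein_meat", "protein_egg", "fats_range", "fats_sfa")

HALF_ADHERENCE_SCORE = 4.5


@dataclass(frozen=True)
class SuggestedCutpoints:
    """Published cut-points behind each guideline predicate (units noted)."""

    dds_min: int = 4                      # food groups
    starchy_units_min: float = 10.0       # food-guide units/d (8500 kJ ref)
    fruitveg_g_min: float = 400.0         # g/d
    legume_g_min: float = 21.4            # g/d (75 g serving, 2 per week)
    dairy_liquid_g_min: float = 400.0     # g/d milk, maas or yoghurt
    cheese_g_min: float = 50.0            # g/d hard cheese alternative
    meat_g_max: float = 90.0              # g/d fish/chicken/lean meat, strict
    meat_require_positive: bool = True
    egg_g_min: float = 4 * 50.0 / 7       # 4 eggs/week x 50 g -> ~28.6 g/d
    fat_pct_low: float = 20.0             # %TE, inclusive
    fat_pct_high: float = 30.0            # %TE, inclusive
    sfa_pct_max: float = 10.0             # %TE, strict
    sugar_full_pct: float = 6.0           # %TE, strict -> full point
    sugar_partial_pct: float = 10.0       # %TE, strict -> half point


DEFAULT_CUTPOINTS = SuggestedCutpoints()


def component_scores(
    exposures: pd.DataFrame,
    participants: pd.DataFrame,
    cutpoints: SuggestedCutpoints = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Score every guideline (and sub-recommendation) for every subject.

    Returns a DataFrame with one column per sub-component, one per
    guideline, plus ``overall`` and ``half_adherent``.
    """
    c = cutpoints
    e = exposures
    p = participants.loc[e.index]
    out = pd.DataFrame(index=e.index.copy())

    out["variety"] = (e["dds"] >= c.dds_min).astype(float)
    out["active"] = p["pa_active"].astype(bool).astype(float)
    out["starchy"] = (e["starchy_units"] >= c.starchy_units_min).astype(float)
    out["fruit_veg"] = (e["fruitveg_g"] >= c.fruitveg_g_min).astype(float)
    out["legumes"] = (e["legume_g"] >= c.legume_g_min).astype(float)
    out["dairy"] = (
        (e["dairy_liquid_g"] >= c.dairy_liquid_g_min)
        | (e["cheese_g"] >= c.cheese_g_min)
    ).astype(float)

    meat_ok = e["fcl_meat_g"] < c.meat_g_max
    if c.meat_require_positive:
        meat_ok &= e["fcl_meat_g"] > 0
    out["protein_meat"] = 0.5 * meat_ok.astype(float)
    out["protein_egg"] = 0.5 * (e["egg_g"] >= c.egg_g_min).astype(float)
    out["protein_foods"] = out["protein_meat"] + out["protein_egg"]

    out["fats_range"] = 0.5 * (
        (e["fat_pct_te"] >= c.fat_pct_low)
        & (e["fat_pct_te"] <= c.fat_pct_high)
    ).astype(float)
    out["fats_sfa"] = 0.5 * (e["sfa_pct_te"] < c.sfa_pct_max).astype(float)
    out["fats"] = out["fats_range"] + out["fats_sfa"]

    sugar = e["sugar_pct_te"].to_numpy(dtype=float)
    out["sugar"] = np.where(
        sugar < c.sugar_full_pct, 1.0,
        np.where(sugar < c.sugar_partial_pct, 0.5, 0.0),
    )

    out["overall"] = out[list(GUIDELINES)].sum(axis=1)
    out["half_adherent"] = out["overall"] > HALF_ADHERENCE_SCORE
    return out


# Primary entry point; the name mirrors the scoring scheme it implements.
score_suggested = component_scores


def score_guideline_suggested(
    guideline_id: str,
    exposures_row: pd.Series,
    participant_row: pd.Series,
    cutpoints: SuggestedCutpoints = DEFAULT_CUTPOINTS,
) -> float:
    """Score a single guideline for a single subject (scalar convenience)."""
    if guideline_id not in GUIDELINES:
        raise DomainError(f"unknown guideline id: {guideline_id!r}")
    scores = component_scores(
        exposures_row.to_frame().T, participant_row.to_frame().T, cutpoints
    )
    return float(scores[guideline_id].iloc[0])


def sensitivity_overall(scores: pd.DataFrame,
                        drop=("legumes", "starchy")) -> pd.Series:
    """Overall score with selected guidelines removed (7-point variant)."""
    keep = [g for g in GUIDELINES if g not in set(drop)]
    return scores[keep].sum(axis=1)


#: Rows of the prevalence report: (label, component column, adherent value).
_PREVALENCE_ROWS = [
    ("variety (DDS >= 4)", "variety", 1.0),
    ("active", "active", 1.0),
    ("starchy (>= 10 units/d)", "starchy", 1.0),
    ("fruit_veg (>= 400 g/d)", "fruit_veg", 1.0),
    ("legumes (>= 21.4 g/d)", "legumes", 1.0),
    ("dairy (>= 400 g or 50 g cheese)", "dairy", 1.0),
    ("protein_foods (both subs)", "protein_foods", 1.0),
    ("  fish/chicken/lean meat < 90 g/d", "protein_meat", 0.5),
    ("  eggs >= 4/week", "protein_egg", 0.5),
    ("fats (both subs)", "fats", 1.0),
    ("  total fat 20-30 %TE", "fats_range", 0.5),
    ("  saturated fat < 10 %TE", "fats_sfa", 0.5),
    ("sugar < 6 %TE (full)", "sugar", 1.0),
    ("  sugar 6-<10 %TE (partial)", "sugar", 0.5),
    ("overall > 4.5 (half adherence)", "half_adherent", True),
]


def adherence_prevalence(scores: pd.DataFrame,
                         status: pd.Series) -> pd.DataFrame:
    """Percent of each arm meeting every guideline and sub-category.

    ``status`` holds ``case``/``control`` aligned with ``scores``. Returns
    a table with ``cases_pct`` and ``controls_pct`` columns.
    """
    status = status.loc[scores.index]
    arms = {"cases_pct": status == "case", "controls_pct": status == "control"}
    for name, mask in arms.items():
        if mask.sum() == 0:
            raise DomainError(f"empty arm for {name}")
    rows = []
    for label, col, value in _PREVALENCE_ROWS:
        row = {"guideline": label}
        for name, mask in arms.items():
            row[name] = 100.0 * float((scores.loc[mask, col] == value).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("guideline")
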