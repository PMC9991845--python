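"""Data-driven tertile adherence scoring (0 / 0.5 / 1; sub-recs halved).

When most of a cohort falls on one side of a published cut-point (five of
nine guidelines showed >= 73 % one-sided adherence in both arms in the
motivating study), binary adherence carries little contrast. This module
re-scores every recommendation on tertiles of a continuous compliance
metric computed **among controls only**: highest (most compliant) tertile
scores 1, middle 0.5, lowest 0. Sub-recommendations are scored the same way
and halved (0, 0.25, 0.5) so that every guideline still contributes at most
one point, and the overall score stays in [0, 9].

Percentiles are the 33rd and 66th of the control distribution. The default
percentile definition is the inverted empirical CDF (the quantile is an
order statistic), which makes tertile scores exactly invariant under any
strictly monotone transform of a metric; ties at a cut-point fall into the
lower tertile. The overall score is likewise categorised by control-score
tertiles (low: <= q33; high: > q66).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import DegenerateCutpointWarning, DomainError
from .suggested import GUIDELINES

#: 400 g liquid dairy is equivalent to 50 g hard cheese in the guideline.
CHEESE_MILK_EQUIVALENT = 400.0 / 50.0

#: Percentile probabilities defining the tertiles.
TERTILE_PROBS = (0.33, 0.66)


@dataclass(frozen=True)
class MetricDef:
    """One continuous compliance metric feeding the tertile scheme."""

    id: str
    guideline: str
    weight: float          # 1.0 for whole guidelines, 0.5 for sub-recs
    orientation: str       # "higher" or "lower" is more compliant


#: Reconstructed metric table (the study's supplementary listing of the
#: exact variables is not public; overridable via ``metric_defs=``).
METRIC_DEFS = (
    MetricDef("variety", "variety", 1.0, "higher"),        # DDS
    MetricDef("active", "active", 1.0, "higher"),          # activity units/wk
    MetricDef("starchy", "starchy", 1.0, "higher"),        # units/d
    MetricDef("fruit_veg", "fruit_veg", 1.0, "higher"),    # g/d
    MetricDef("legumes", "legumes", 1.0, "higher"),        # g/d
    MetricDef("dairy", "dairy", 1.0, "higher"),            # milk-equiv g/d
    MetricDef("protein_meat", "protein_foods", 0.5, "lower"),   # g/d
    MetricDef("protein_egg", "protein_foods", 0.5, "higher"),   # g/d
    MetricDef("fats_range", "fats", 0.5, "lower"),   # %TE outside [20, 30]
    MetricDef("fats_sfa", "fats", 0.5, "lower"),     # %TE
    MetricDef("sugar", "sugar", 1.0, "lower"),       # %TE
)


def compliance_metrics(
    exposures: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Continuous compliance metric per subject and recommendation."""
    p = participants.loc[exposures.index]
    e = exposures
    fat = e["fat_pct_te"].to_numpy(dtype=float)
    out = pd.DataFrame(index=e.index.copy())
    out["variety"] = e["dds"].astype(float)
    out["active"] = p["pa_metric"].astype(float)
    out["starchy"] = e["starchy_units"].astype(float)
    out["fruit_veg"] = e["fruitveg_g"].astype(float)
    out["legumes"] = e["legume_g"].astype(float)
    out["dairy"] = (
        e["dairy_liquid_g"] + CHEESE_MILK_EQUIVALENT * e["cheese_g"]
    ).astype(float)
    out["protein_meat"] = e["fcl_meat_g"].astype(float)
    out["protein_egg"] = e["egg_g"].astype(float)
    out["fats_range"] = (
        np.maximum(0.0, 20.0 - fat) + np.maximum(0.0, fat - 30.0)
    )
    out["fats_sfa"] = e["sfa_pct_te"].astype(float)
    out["sugar"] = e["sugar_pct_te"].astype(float)
    return out


@dataclass
class TertileCutpoints:
    """Oriented 33rd/66th percentiles of the control metric distributions.

    Cut-points are stored on the *oriented* scale (lower-is-better metrics
    are negated), so scoring is uniformly "above q66 -> 1".
    """

    q33: dict[str, float]
    q66: dict[str, float]
    orientations: dict[str, str]
    n_controls: int
    method: str = "inverted_cdf"
    metric_defs: tuple[MetricDef, ...] = field(default=METRIC_DEFS)

    def to_yaml(self, path) -> None:
        payload = {
            "method": self.method,
            "n_controls": int(self.n_controls),
            "metrics": {
                m: {
                    "q33": float(self.q33[m]),
                    "q66": float(self.q66[m]),
                    "orientation": self.orientations[m],
                }
                for m in self.q33
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _orient(values: np.ndarray, orientation: str) -> np.ndarray:
    return values if orientation == "higher" else -values


def derive_cutpoints(
    control_metrics: pd.DataFrame,
    metric_defs: tuple[MetricDef, ...] = METRIC_DEFS,
    method: str = "inverted_cdf",
) -> TertileCutpoints:
    """Empirical 33rd/66th percentiles of each metric among controls.

    Raises :class:`DomainError` with fewer than three finite controls;
    warns (:class:`DegenerateCutpointWarning`) when a metric is constant so
    that both cut-points coincide.
    """
    q33, q66, orientations = {}, {}, {}
    for m in metric_defs:
        vals = control_metrics[m.id].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            raise DomainError(
                f"metric {m.id!r}: need >= 3 controls with finite values"
            )
        w = _orient(vals, m.orientation)
        lo, hi = np.quantile(w, TERTILE_PROBS, method=method)
        if lo == hi:
            warnings.warn(
                f"metric {m.id!r}: degenerate tertile cut-points "
                f"(q33 == q66 == {lo:g})",
                DegenerateCutpointWarning,
                stacklevel=2,
            )
        q33[m.id], q66[m.id] = float(lo), float(hi)
        orientations[m.id] = m.orientation
    return TertileCutpoints(
        q33=q33, q66=q66, orientations=orientations,
        n_controls=len(control_metrics), method=method,
        metric_defs=metric_defs,
    )


def score_metric_tertile(values, q33: float, q66: float,
                         orientation: str = "higher") -> np.ndarray:
    """Map metric values onto tertile scores {0, 0.5, 1}.

    Values above the 66th percentile (in the compliant direction) score 1,
    above the 33rd score 0.5, otherwise 0; ties fall to the lower tertile.
    NaN propagates.
    """
    w = _orient(np.asarray(values, dtype=float), orientation)
    s = np.where(w > q66, 1.0, np.where(w > q33, 0.5, 0.0))
    return np.where(np.isnan(w), np.nan, s)


def score_tertile(
    metrics: pd.DataFrame, cutpoints: TertileCutpoints
) -> pd.DataFrame:
    """Tertile-scheme components and overall score for every subject.

    Sub-recommendation columns hold their *weighted* contribution (0, 0.25
    or 0.5); guideline columns sum their sub-recommendations. Subjects with
    a NaN metric are excluded from that component (flagged ``incomplete``)
    and their overall score sums the remaining components.
    """
    out = pd.DataFrame(index=metrics.index.copy())
    for m in cutpoints.metric_defs:
        raw = score_metric_tertile(
            metrics[m.id], cutpoints.q33[m.id], cutpoints.q66[m.id],
            cutpoints.orientations[m.id],
        )
        out[m.id] = m.weight * raw
    for g in GUIDELINES:
        subs = [m.id for m in cutpoints.metric_defs if m.guideline == g]
        if subs == [g]:
            continue
        out[g] = out[subs].sum(axis=1, skipna=True)
    component_cols = list(GUIDELINES)
    out["incomplete"] = out[component_cols].isna().any(axis=1)
    out["overall"] = out[component_cols].sum(axis=1, skipna=True)
    return out


def overall_tertile_category(
    overall: pd.Series,
    control_ids,
    method: str = "inverted_cdf",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Low/mid/high adherence category from control overall-score tertiles.

    Returns ``(frame, (q33, q66))`` where ``frame`` has ``overall`` and
    ``category`` columns; low means score <= q33, high means score > q66.
    """
    controls = overall.loc[control_ids].to_numpy(dtype=float)
    if controls.size < 3:
        raise DomainError("need >= 3 controls to derive overall tertiles")
    q33, q66 = np.quantile(controls, TERTILE_PROBS, method=method)
    if q33 == q66:
        warnings.warn(
            "overall-score tertile boundaries are degenerate "
            f"(q33 == q66 == {q33:g})",
            DegenerateCutpointWarning,
            stacklevel=2,
        )
    vals = overall.to_numpy(dtype=float)
    category = np.where(vals > q66, "high",
                        np.where(vals > q33, "mid", "low"))
    frame = pd.DataFrame(
        {"overall": overall, "category": category}, index=overall.index
    )
    return frame, (float(q33), float(q66))


def skewness_report(
    suggested_scores: pd.DataFrame,
    status: pd.Series,
    threshold: float = 0.73,
) -> pd.DataFrame:
    """Flag guidelines whose suggested-scheme scoring is highly one-sided.

    A guideline is flagged when a single score category holds at least
    ``threshold`` (default 73 %) of subjects in *both* arms — the skew
    regime that motivates tertile-based rescoring.
    """
    status = status.loc[suggested_scores.index]
    rows = []
    for g in GUIDELINES:
        shares = {}
        for arm, label in (("case", "max_share_cases"),
                           ("control", "max_share_controls")):
            vals = suggested_scores.loc[status == arm, g]
            shares[label] = float(
                vals.value_counts(normalize=True).max()) if len(vals) else np.nan
        rows.append({
            "guideline": g,
            **shares,
            "skewed": bool(
                shares["max_share_cases"] >= threshold
                and shares["max_share_controls"] >= threshold
            ),
        })
    return pd.DataFrame(rows).set_index("guideline")
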