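"""End-to-end orchestration: data -> exposures -> scores -> models -> report.

:func:`run_pipeline` runs every stage of the analysis on either a synthetic
study (from a :class:`~safbdg.simulate.SimulationConfig`) or three study
CSVs, and writes a deterministic artifact set into the output directory:

- ``exposures.csv`` — per-subject food-group exposures
- ``scores_suggested.csv`` / ``prevalence.csv`` / ``skewness.csv``
- ``cutpoints.yaml`` / ``scores_tertile.csv`` / ``categories.csv``
- ``misreporting.csv``
- ``models.csv`` — tidy per-stratum OR / CI / p rows
- ``report.md`` — human-readable summary
- ``manifest.json`` — seed, versions and SHA-256 of every artifact

Every stage logs one structured line with its in/out counts; stage errors
are re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import SafbdgError
from .food_groups import aggregate_groups
from .io import GroupMapping, StudyTable, compute_bmi, read_study, write_study
from .misreporting import GoldbergParams, classify_study
from .simulate import SimulationConfig, simulate_study, toy_foods
from .stats import (
    confounder_screen,
    fit_category_contrasts,
    fit_logit,
    interaction_test,
    trend_test,
)
from .suggested import adherence_prevalence, score_suggested
from .tertile import (
    compliance_metrics,
    derive_cutpoints,
    overall_tertile_category,
    score_tertile,
    skewness_report,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and where to put it (exactly one input source)."""

    out_dir: str | Path
    simulation: SimulationConfig | None = None
    input_paths: tuple[str, str, str] | None = None  # participants/intakes/nutrients
    mapping: GroupMapping | None = None
    seed: int = 0
    covariate_candidates: tuple[str, ...] = (
        "waist_cm", "energy_kj", "alcohol_g", "income_band", "ethnicity",
    )
    screen_threshold: float = 0.10
    goldberg: GoldbergParams = field(default_factory=GoldbergParams)
    run_strata: bool = True

    def validate(self) -> "PipelineConfig":
        if (self.simulation is None) == (self.input_paths is None):
            raise SafbdgError(
                "configure exactly one input source "
                "(simulation or input_paths)"
            )
        return self


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise SafbdgError(f"pipeline stage {name!r} failed: {err}") from err
    return wrap


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return "" if np.isnan(v) else floatfmt.format(v)
        return str(v)

    df = df.reset_index()
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def _result_rows(model: str, stratum: str, result) -> list[dict]:
    rows = []
    for term, row in result.summary.iterrows():
        rows.append({
            "model": model, "stratum": stratum, "term": term,
            "or": row["or_"], "ci_low": row["ci_low"],
            "ci_high": row["ci_high"], "p": row["p"],
            "n": result.n,
            "n_informative_pairs": result.n_informative_pairs,
            "note": "",
        })
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns a bundle of objects and paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: input
    if config.simulation is not None:
        synthetic = _stage("simulate")(
            simulate_study, config.simulation, config.seed)
        study: StudyTable = synthetic.study
        truth = synthetic.truth
    else:
        study = _stage("read")(read_study, *config.input_paths)
        synthetic, truth = None, None
    mapping = config.mapping or toy_foods()
    logger.info("pipeline: %d subjects in, %d pairs",
                study.n_subjects, study.n_pairs)

    # -- stage: exposures
    exposures = _stage("aggregate")(
        aggregate_groups, study.intakes, study.nutrients, mapping)
    logger.info("aggregate: %d subjects out", len(exposures))

    # -- stage: suggested scoring
    scores_sug = _stage("score_suggested")(
        score_suggested, exposures, study.participants)
    prevalence = _stage("prevalence")(
        adherence_prevalence, scores_sug, study.participants["status"])
    skew = _stage("skewness")(
        skewness_report, scores_sug, study.participants["status"])

    # -- stage: tertile scoring (cut-points from controls only)
    metrics = _stage("metrics")(
        compliance_metrics, exposures, study.participants)
    control_ids = study.participants.index[
        study.participants["status"] == "control"]
    cutpoints = _stage("cutpoints")(derive_cutpoints, metrics.loc[control_ids])
    scores_ter = _stage("score_tertile")(score_tertile, metrics, cutpoints)
    categories, boundaries = _stage("categories")(
        overall_tertile_category, scores_ter["overall"], control_ids)
    logger.info("tertile: overall boundaries q33=%.3f q66=%.3f", *boundaries)

    # -- stage: misreporting
    misreport = _stage("misreport")(
        classify_study, study.participants, study.nutrients, config.goldberg)

    # -- stage: analysis table
    analysis = study.participants.copy()
    analysis["category"] = categories["category"]
    analysis["category_code"] = categories["category"].map(
        {"low": 0.0, "mid": 1.0, "high": 2.0})
    analysis["energy_kj"] = study.nutrients["energy_kj"]
    analysis["reporting_status"] = misreport["reporting_status"]
    analysis["bmi"] = compute_bmi(
        analysis["weight_kg"].to_numpy(), analysis["height_cm"].to_numpy())
    analysis["obese"] = analysis["bmi"] >= 30.0
    analysis["postmenopausal"] = (analysis["menopausal"] == "post")

    # -- stage: models
    model_rows: list[dict] = []

    def record(model, stratum, fn, *args, **kwargs):
        try:
            res = fn(*args, **kwargs)
        except SafbdgError as err:
            logger.warning("model %s/%s failed: %s", model, stratum, err)
            model_rows.append({
                "model": model, "stratum": stratum, "term": "",
                "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "n": np.nan, "n_informative_pairs": np.nan,
                "note": str(err),
            })
            return None
        model_rows.extend(_result_rows(model, stratum, res))
        return res

    crude = record("crude", "overall", fit_category_contrasts,
                   analysis, "category", covariates=(), conditional=True)

    screen = _stage("confounder_screen")(
        confounder_screen, analysis, "category_code",
        list(config.covariate_candidates), True, config.screen_threshold)
    selected = tuple(screen.selected)
    logger.info("screen: selected %s", list(selected))

    adjusted = record("adjusted", "overall", fit_category_contrasts,
                      analysis, "category", covariates=selected,
                      conditional=True)
    trend = None
    try:
        trend = trend_test(analysis, "category", covariates=selected,
                           conditional=True)
        model_rows.append({
            "model": "adjusted_trend", "stratum": "overall",
            "term": "ordinal_slope", "or": np.exp(trend.slope),
            "ci_low": np.nan, "ci_high": np.nan, "p": trend.p_trend,
            "n": trend.fit_ordinal.n,
            "n_informative_pairs": trend.fit_ordinal.n_informative_pairs,
            "note": "",
        })
    except SafbdgError as err:
        logger.warning("trend test failed: %s", err)

    if config.run_strata:
        # menopausal and obesity strata break the matching -> unconditional
        uncond_covs = tuple(c for c in selected)
        for stratum, mask in (
            ("postmenopausal", analysis["menopausal"] == "post"),
            ("premenopausal", analysis["menopausal"] == "pre"),
            ("obese", analysis["obese"]),
            ("non_obese", ~analysis["obese"]),
        ):
            covs = tuple(c for c in uncond_covs
                         if not (stratum in ("obese", "non_obese")
                                 and c == "waist_cm"))
            record("adjusted_unconditional", stratum,
                   fit_category_contrasts, analysis[mask], "category",
                   covariates=covs, conditional=False)
        # receptor strata keep complete pairs -> conditional
        er_pairs = analysis.loc[
            (analysis["status"] == "case") & (analysis["er"] == "positive"),
            "pair_id"]
        record("adjusted", "er_positive", fit_category_contrasts,
               analysis[analysis["pair_id"].isin(er_pairs)], "category",
               covariates=selected, conditional=True)
        # interactions
        case_post = analysis.loc[analysis["status"] == "case"] \
            .set_index("pair_id")["postmenopausal"]
        analysis["_pair_post"] = analysis["pair_id"].map(case_post).astype(float)
        try:
            p_int, _ = interaction_test(
                analysis, "category_code", "_pair_post", conditional=True)
            model_rows.append({
                "model": "interaction", "stratum": "menopausal",
                "term": "category_x_postmenopausal", "or": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": p_int,
                "n": np.nan, "n_informative_pairs": np.nan, "note": "",
            })
        except SafbdgError as err:
            logger.warning("menopausal interaction failed: %s", err)
        try:
            p_int, _ = interaction_test(
                analysis, "category_code", "obese", conditional=False)
            model_rows.append({
                "model": "interaction", "stratum": "obesity",
                "term": "category_x_obese", "or": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": p_int,
                "n": np.nan, "n_informative_pairs": np.nan, "note": "",
            })
        except SafbdgError as err:
            logger.warning("obesity interaction failed: %s", err)

    models = pd.DataFrame(model_rows)

    # -- stage: artifacts
    artifacts = {
        "exposures.csv": exposures,
        "scores_suggested.csv": scores_sug,
        "prevalence.csv": prevalence,
        "skewness.csv": skew,
        "scores_tertile.csv": scores_ter,
        "categories.csv": categories,
        "misreporting.csv": misreport,
        "models.csv": models.set_index("model"),
        "screen.csv": screen.table,
    }
    paths = {}
    for name, frame in artifacts.items():
        path = out / name
        frame.to_csv(path)
        paths[name] = path
    cutpoints.to_yaml(out / "cutpoints.yaml")
    paths["cutpoints.yaml"] = out / "cutpoints.yaml"
    if config.simulation is not None:
        truth.to_csv(out / "truth.csv")
        paths["truth.csv"] = out / "truth.csv"
        study_paths = write_study(study, out / "study")
        paths.update({f"study/{k}.csv": v for k, v in study_paths.items()})

    report = [
        "# Guideline-adherence analysis report",
        "",
        f"Subjects: {study.n_subjects}; pairs: {study.n_pairs}; "
        f"seed: {config.seed}",
        f"Overall tertile-score boundaries (controls): "
        f"low <= {boundaries[0]:.2f}, high > {boundaries[1]:.2f}",
        "",
        "## Adherence prevalence (suggested cut-points)",
        _md_table(prevalence.round(1), "{:.1f}"),
        "",
        "## Skewed guidelines (>= 73 % one category in both arms)",
        _md_table(skew),
        "",
        "## Confounder screen (10 % change-in-estimate)",
        _md_table(screen.table),
        "",
        "## Models",
        _md_table(models.set_index("model")),
        "",
    ]
    (out / "report.md").write_text("\n".join(report), encoding="utf-8")
    paths["report.md"] = out / "report.md"

    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "n_subjects": int(study.n_subjects),
        "n_pairs": int(study.n_pairs),
        "overall_boundaries": [round(b, 10) for b in boundaries],
        "artifacts": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(paths.items())
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")

    return {
        "study": study,
        "truth": truth,
        "exposures": exposures,
        "scores_suggested": scores_sug,
        "prevalence": prevalence,
        "skewness": skew,
        "cutpoints": cutpoints,
        "scores_tertile": scores_ter,
        "categories": categories,
        "boundaries": boundaries,
        "misreporting": misreport,
        "screen": screen,
        "models": models,
        "crude": crude,
        "adjusted": adjusted,
        "trend": trend,
        "manifest": manifest,
        "paths": paths,
    }
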