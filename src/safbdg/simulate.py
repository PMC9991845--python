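"""Synthetic matched case-control studies with known truth.

The generator emulates the structure the analysis pipeline assumes: 1:1
pairs matched on age (+/- 5 years) and area of residence; right-skewed,
zero-inflated food-group intakes (most guidelines show strongly one-sided
adherence); arm-specific covariate distributions (waist circumference, HIV
prevalence, alcohol); injected energy under-/over-reporting; and a
configurable conditional odds ratio linking the adherence tertile to case
status.

Case status is assigned *within* each pair by the conditional logistic
model itself: both pair members receive exchangeable diet profiles, their
overall adherence tertile category c in {0, 1, 2} is computed against
reference cut-points, and the case label goes to member A with probability
exp(b*cA) / (exp(b*cA) + exp(b*cB)) where b = log(OR)/2. The conditional
likelihood of the resulting data is then *exactly* the conditional
logistic model with a per-tertile-step log odds of b, so the high-vs-low
estimand equals the configured OR by construction.

Lognormal intake parameters were fixed analytically so that control-arm
adherence prevalences sit near the levels the guideline-adherence
literature reports for this population (legumes ~23 %, eggs ~47 %,
fish/chicken/lean meat ~73 %, dairy ~13 %, fat-in-range ~45 %,
starchy ~40 %); see docs/methods.md.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tertile as tert
from .exceptions import DomainError
from .io import GroupMapping, StudyTable, read_mapping
from .misreporting import GoldbergParams, bmr_schofield, goldberg_limits

__all__ = [
    "GroupIntakeParams", "SimulationConfig", "SyntheticStudy",
    "default_group_params", "simulate_exposure_pairs", "simulate_study",
    "toy_foods",
]


@dataclass(frozen=True)
class GroupIntakeParams:
    """Zero-inflated lognormal intake model for one food group.

    ``consume_p`` is the probability of any consumption (1 - zero
    inflation); consumers draw ``LogNormal(log(median_g), sigma)`` g/d
    (units/d for the starchy group).
    """

    consume_p: float
    median_g: float
    sigma: float


def default_group_params() -> dict[str, GroupIntakeParams]:
    return {
        "vita_fruitveg": GroupIntakeParams(0.80, 35.0, 0.9),
        "other_veg": GroupIntakeParams(0.95, 90.0, 0.7),
        "other_fruit": GroupIntakeParams(0.70, 60.0, 0.9),
        "legumes": GroupIntakeParams(0.75, 12.0, 1.1),
        "dairy_liquid": GroupIntakeParams(0.85, 140.0, 1.0),
        "cheese": GroupIntakeParams(0.30, 5.0, 1.0),
        "fcl_meat": GroupIntakeParams(0.97, 55.0, 0.7),
        "other_meat": GroupIntakeParams(0.60, 30.0, 0.8),
        "egg": GroupIntakeParams(0.85, 32.0, 0.9),
        "starchy_units": GroupIntakeParams(1.0, 8.9, 0.45),
        "oils": GroupIntakeParams(0.95, 15.0, 0.6),
        "sugary_other": GroupIntakeParams(0.90, 80.0, 0.8),
    }


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study` (defaults mirror the
    motivating study's design: 396 pairs, protective overall OR 0.56)."""

    n_pairs: int = 396
    or_overall: float = 0.56
    or_postmenopausal: float | None = None
    or_er_positive: float | None = None
    n_reference: int = 600

    group_params: dict[str, GroupIntakeParams] = field(
        default_factory=default_group_params)
    pa_median: float = 20.0
    pa_sigma: float = 0.9
    pa_active_threshold: float = 33.0
    fat_pct_mean: float = 28.0
    fat_pct_sd: float = 8.0
    sfa_frac_a: float = 6.6
    sfa_frac_b: float = 13.4
    sugar_pct_median: float = 8.5
    sugar_pct_sigma: float = 0.55
    dds_threshold_g: float = 15.0

    age_mean: float = 49.0
    age_sd: float = 11.0
    menopause_age: float = 50.0
    menopausal_unknown_p: float = 0.025
    waist_case: tuple[float, float] = (93.3, 13.8)
    waist_control: tuple[float, float] = (95.8, 13.7)
    height_mean: float = 158.5
    height_sd: float = 6.5
    bmi_mean: float = 29.5
    bmi_sd: float = 6.5
    hiv_case: float = 0.165
    hiv_control: float = 0.226
    smoker_p: float = 0.10
    alcohol_p_case: float = 0.30
    alcohol_p_control: float = 0.35
    alcohol_median_case: float = 18.0
    alcohol_median_control: float = 13.1
    alcohol_sigma: float = 0.8
    ethnicity_freqs: dict[str, float] = field(default_factory=lambda: {
        "zulu": 0.35, "sotho": 0.25, "tswana": 0.12, "xhosa": 0.10,
        "tsonga": 0.08, "venda": 0.05, "ndebele": 0.05,
    })
    income_freqs: dict[str, float] = field(default_factory=lambda: {
        "R1-R3000": 0.55, "R3001-R6000": 0.30, "R6001+": 0.15,
    })
    education_freqs: dict[str, float] = field(default_factory=lambda: {
        "none_primary": 0.25, "high_school": 0.55, "college_plus": 0.20,
    })
    er_pos_p: float = 0.753
    pr_pos_p: float = 0.664
    her2_pos_p: float = 0.20

    under_report_case: float = 0.131
    under_report_control: float = 0.116
    over_report_case: float = 0.240
    over_report_control: float = 0.270
    goldberg: GoldbergParams = field(default_factory=GoldbergParams)

    def validate(self) -> "SimulationConfig":
        if self.n_pairs < 3:
            raise DomainError("n_pairs must be >= 3")
        for name in ("or_overall", "or_postmenopausal", "or_er_positive"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise DomainError(f"{name} must be positive")
        probs = [
            self.under_report_case, self.under_report_control,
            self.over_report_case, self.over_report_control,
            self.hiv_case, self.hiv_control, self.smoker_p,
            self.alcohol_p_case, self.alcohol_p_control,
            self.er_pos_p, self.pr_pos_p, self.her2_pos_p,
            self.menopausal_unknown_p,
        ] + [g.consume_p for g in self.group_params.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise DomainError("probabilities must lie in [0, 1]")
        if self.under_report_case + self.over_report_case > 1 \
                or self.under_report_control + self.over_report_control > 1:
            raise DomainError("reporting fractions exceed 1 within an arm")
        return self

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class SyntheticStudy:
    """A generated study plus the truth record behind it."""

    study: StudyTable
    truth: pd.DataFrame
    cutpoints: tert.TertileCutpoints
    overall_boundaries: tuple[float, float]
    config: SimulationConfig
    seed: int


def toy_foods() -> GroupMapping:
    """The bundled ~45-item toy food list as a validated mapping."""
    path = importlib.resources.files("safbdg.data") / "toy_foods.yaml"
    with importlib.resources.as_file(path) as p:
        return read_mapping(p)


def simulate_exposure_pairs(
    n_pairs: int,
    or_high_vs_low: float,
    seed=None,
    category_probs=(1 / 3, 1 / 3, 1 / 3),
) -> pd.DataFrame:
    """Category-level matched pairs at an exact conditional OR.

    Each pair member draws an adherence category in {0, 1, 2}; the case
    label is assigned by the conditional model with per-step log odds
    ``log(OR)/2``. Returns subject-level rows with ``pair_id``, ``status``
    and numeric ``category``. This light-weight path is what replicate
    studies (parameter recovery, test calibration) are built on.
    """
    if or_high_vs_low <= 0:
        raise DomainError("odds ratio must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    probs = np.asarray(category_probs, dtype=float)
    probs = probs / probs.sum()
    beta = math.log(or_high_vs_low) / 2.0
    cats = rng.choice(3, size=(n_pairs, 2), p=probs).astype(float)
    wa = np.exp(beta * cats[:, 0])
    wb = np.exp(beta * cats[:, 1])
    a_is_case = rng.random(n_pairs) < wa / (wa + wb)
    case_cat = np.where(a_is_case, cats[:, 0], cats[:, 1])
    ctrl_cat = np.where(a_is_case, cats[:, 1], cats[:, 0])
    pair_ids = [f"P{i:05d}" for i in range(n_pairs)]
    return pd.DataFrame({
        "pair_id": pair_ids * 2,
        "status": ["case"] * n_pairs + ["control"] * n_pairs,
        "category": np.concatenate([case_cat, ctrl_cat]),
    })


def _zero_inflated_lognormal(rng, params: GroupIntakeParams, n: int):
    consumed = rng.random(n) < params.consume_p
    amounts = rng.lognormal(math.log(params.median_g), params.sigma, n)
    return np.where(consumed, amounts, 0.0)


def _split_items(rng, totals: np.ndarray, items: list[str]) -> pd.DataFrame:
    """Distribute group totals over member items with Dirichlet shares."""
    shares = rng.dirichlet(np.full(len(items), 4.0), size=totals.shape[0])
    return pd.DataFrame(totals[:, None] * shares, columns=items)


def _choice(rng, freqs: dict[str, float], n: int) -> np.ndarray:
    keys = list(freqs)
    p = np.asarray([freqs[k] for k in keys], dtype=float)
    return rng.choice(np.asarray(keys, dtype=object), size=n, p=p / p.sum())


def simulate_study(config: SimulationConfig | None = None,
                   seed: int = 0) -> SyntheticStudy:
    """Generate a full matched study; fully reproducible from ``seed``."""
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(seed)
    mapping = toy_foods()
    n_pairs = config.n_pairs
    n_ref = config.n_reference
    m = n_ref + 2 * n_pairs

    # --- exchangeable diet/activity profiles for reference + study members
    gp = config.group_params
    draws = {
        key: _zero_inflated_lognormal(rng, gp[key], m)
        for key in sorted(gp)
    }
    pa_metric = rng.lognormal(math.log(config.pa_median), config.pa_sigma, m)
    fat_pct = np.clip(
        rng.normal(config.fat_pct_mean, config.fat_pct_sd, m), 8.0, 55.0)
    sfa_frac = rng.beta(config.sfa_frac_a, config.sfa_frac_b, m)
    sugar_pct = np.clip(
        rng.lognormal(math.log(config.sugar_pct_median),
                      config.sugar_pct_sigma, m), 0.0, 35.0)

    # item split (study members need item-level intakes; reference rows get
    # them too so that FAO totals are computed the same way throughout)
    table = mapping.table
    starchy_items = mapping.items_in_family("starchy")
    unit_g = table.loc[starchy_items, "starchy_unit_g"].to_numpy(dtype=float)
    starchy_shares = rng.dirichlet(
        np.full(len(starchy_items), 4.0), size=m)
    starchy_grams = pd.DataFrame(
        draws["starchy_units"][:, None] * starchy_shares * unit_g[None, :],
        columns=starchy_items,
    )

    def items_other(dds_group):
        sel = table[(table["dds_group"] == dds_group)
                    & (table["family"].isna())]
        return list(sel.index)

    item_blocks = [
        starchy_grams,
        _split_items(rng, draws["fcl_meat"],
                     mapping.items_in_family("fish_chicken_leanmeat")),
        _split_items(rng, draws["other_meat"], items_other(2)),
        _split_items(rng, draws["dairy_liquid"],
                     mapping.items_in_family("dairy_liquid")),
        _split_items(rng, draws["cheese"],
                     mapping.items_in_family("hard_cheese")),
        _split_items(rng, draws["egg"], mapping.items_in_family("egg")),
        _split_items(rng, draws["vita_fruitveg"],
                     mapping.items_in_dds_group(5)),
        _split_items(rng, draws["legumes"], mapping.items_in_family("legume")),
        _split_items(rng, draws["other_veg"], mapping.items_in_dds_group(7)),
        _split_items(rng, draws["other_fruit"], mapping.items_in_dds_group(8)),
        _split_items(rng, draws["oils"], items_other(9)),
        _split_items(rng, draws["sugary_other"],
                     list(table.index[table["dds_group"].isna()])),
    ]
    intake_items = pd.concat(item_blocks, axis=1)[mapping.items]

    # --- exposures and adherence-tertile truth
    fao = {
        1: starchy_grams.sum(axis=1).to_numpy(),
        2: draws["fcl_meat"] + draws["other_meat"],
        3: draws["dairy_liquid"] + draws["cheese"],
        4: draws["egg"],
        5: draws["vita_fruitveg"],
        6: draws["legumes"],
        7: draws["other_veg"],
        8: draws["other_fruit"],
        9: draws["oils"],
    }
    dds = (np.column_stack([fao[g] for g in range(1, 10)])
           >= config.dds_threshold_g).sum(axis=1)
    exposures = pd.DataFrame({
        "fruitveg_g": draws["vita_fruitveg"] + draws["other_veg"]
        + draws["other_fruit"],
        "legume_g": draws["legumes"],
        "dairy_liquid_g": draws["dairy_liquid"],
        "cheese_g": draws["cheese"],
        "fcl_meat_g": draws["fcl_meat"],
        "egg_g": draws["egg"],
        "starchy_units": draws["starchy_units"],
        "dds": dds.astype(float),
        "fat_pct_te": fat_pct,
        "sfa_pct_te": fat_pct * sfa_frac,
        "sugar_pct_te": sugar_pct,
    })
    pseudo_participants = pd.DataFrame(
        {"pa_metric": pa_metric}, index=exposures.index)
    metrics = tert.compliance_metrics(exposures, pseudo_participants)
    cutpoints = tert.derive_cutpoints(metrics.iloc[:n_ref])
    scores = tert.score_tertile(metrics, cutpoints)
    ref_overall = scores["overall"].iloc[:n_ref].to_numpy()
    q33, q66 = np.quantile(ref_overall, tert.TERTILE_PROBS,
                           method="inverted_cdf")
    category = np.where(scores["overall"] > q66, 2,
                        np.where(scores["overall"] > q33, 1, 0)).astype(float)

    # --- pair structure, strata and conditional case assignment
    s = slice(n_ref, m)  # study members; pair i = rows (2i, 2i+1) of this
    cat_members = category[s].reshape(n_pairs, 2)
    base_age = np.clip(rng.normal(config.age_mean, config.age_sd, n_pairs),
                       25.0, 79.0)
    member_age = np.repeat(base_age, 2) + rng.uniform(-2.5, 2.5, 2 * n_pairs)
    postmeno_pair = base_age >= config.menopause_age
    er_pos_pair = rng.random(n_pairs) < config.er_pos_p

    theta = np.full(n_pairs, config.or_overall)
    if config.or_postmenopausal is not None:
        theta[postmeno_pair] = config.or_postmenopausal
    if config.or_er_positive is not None:
        theta[er_pos_pair] = config.or_er_positive
    beta = np.log(theta) / 2.0
    wa = np.exp(beta * cat_members[:, 0])
    wb = np.exp(beta * cat_members[:, 1])
    a_is_case = rng.random(n_pairs) < wa / (wa + wb)
    is_case = np.zeros(2 * n_pairs, dtype=bool)
    is_case[0::2] = a_is_case
    is_case[1::2] = ~a_is_case

    # --- covariates (arm-specific where the study showed arm differences)
    n_sub = 2 * n_pairs
    waist = np.where(
        is_case,
        rng.normal(*config.waist_case, n_sub),
        rng.normal(*config.waist_control, n_sub),
    ).clip(min=55.0)
    height = rng.normal(config.height_mean, config.height_sd, n_sub)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n_sub),
                  16.0, 55.0)
    weight = bmi * (height / 100.0) ** 2
    hiv = np.where(
        rng.random(n_sub) < np.where(is_case, config.hiv_case,
                                     config.hiv_control),
        "positive", "negative",
    )
    smoker = rng.random(n_sub) < config.smoker_p
    ethnicity = _choice(rng, config.ethnicity_freqs, n_sub)
    income = _choice(rng, config.income_freqs, n_sub)
    education = _choice(rng, config.education_freqs, n_sub)
    drinks = rng.random(n_sub) < np.where(
        is_case, config.alcohol_p_case, config.alcohol_p_control)
    alcohol_amount = np.where(
        is_case,
        rng.lognormal(math.log(config.alcohol_median_case),
                      config.alcohol_sigma, n_sub),
        rng.lognormal(math.log(config.alcohol_median_control),
                      config.alcohol_sigma, n_sub),
    )
    alcohol = np.where(drinks, alcohol_amount, 0.0)

    menopausal = np.where(member_age >= config.menopause_age, "post", "pre")
    menopausal = np.where(
        rng.random(n_sub) < config.menopausal_unknown_p, "unknown",
        menopausal)
    er = np.where(is_case,
                  np.where(np.repeat(er_pos_pair, 2), "positive", "negative"),
                  "unknown")
    pr = np.where(is_case,
                  np.where(rng.random(n_sub) < config.pr_pos_p,
                           "positive", "negative"),
                  "unknown")
    her2 = np.where(is_case,
                    np.where(rng.random(n_sub) < config.her2_pos_p,
                             "positive", "negative"),
                    "unknown")

    # --- energy reporting: draw a class per subject, then an EI/BMR ratio
    # strictly inside that class's Goldberg region
    lower, upper = goldberg_limits(config.goldberg)
    p_under = np.where(is_case, config.under_report_case,
                       config.under_report_control)
    p_over = np.where(is_case, config.over_report_case,
                      config.over_report_control)
    u = rng.random(n_sub)
    reporting = np.where(u < p_under, "under",
                         np.where(u < p_under + p_over, "over", "plausible"))
    ratio = np.clip(
        config.goldberg.pal * np.exp(rng.normal(0.0, 0.18, n_sub)),
        lower * 1.02, upper * 0.98)
    ratio = np.where(reporting == "under",
                     lower * rng.uniform(0.50, 0.95, n_sub), ratio)
    ratio = np.where(reporting == "over",
                     upper * rng.uniform(1.05, 1.50, n_sub), ratio)
    bmr = bmr_schofield("female", member_age, weight)
    energy = ratio * bmr

    study_idx = np.arange(n_ref, m)
    subject_ids = [f"S{i:05d}" for i in range(n_sub)]
    pair_ids = [f"P{i:05d}" for i in np.repeat(np.arange(n_pairs), 2)]

    participants = pd.DataFrame({
        "pair_id": pair_ids,
        "status": np.where(is_case, "case", "control"),
        "age": member_age,
        "menopausal": menopausal,
        "er": er, "pr": pr, "her2": her2,
        "ethnicity": ethnicity,
        "income_band": income,
        "education": education,
        "smoker": smoker,
        "waist_cm": waist,
        "height_cm": height,
        "weight_kg": weight,
        "hiv": hiv,
        "pa_metric": pa_metric[s],
        "pa_active": pa_metric[s] >= config.pa_active_threshold,
        "alcohol_g": alcohol,
    }, index=pd.Index(subject_ids, name="subject_id"))

    intakes = intake_items.iloc[study_idx].copy()
    intakes.index = participants.index

    fat_g = fat_pct[s] / 100.0 * energy / 37.0
    nutrients = pd.DataFrame({
        "energy_kj": energy,
        "fat_g": fat_g,
        "sfa_g": sfa_frac[s] * fat_g,
        "added_sugar_g": sugar_pct[s] / 100.0 * energy / 17.0,
        "alcohol_g": alcohol,
    }, index=participants.index)

    study = StudyTable(
        participants=participants,
        intakes=intakes,
        nutrients=nutrients,
        provenance={"source": "simulate_study", "seed": int(seed),
                    "schema_version": 1},
    ).validate()

    labels = np.asarray(["low", "mid", "high"], dtype=object)
    truth = pd.DataFrame({
        "pair_id": pair_ids,
        "status": participants["status"],
        "true_category": labels[category[s].astype(int)],
        "true_category_code": category[s].astype(int),
        "true_overall_score": scores["overall"].iloc[study_idx].to_numpy(),
        "reporting_class": reporting,
        "theta_pair": np.repeat(theta, 2),
        "postmenopausal_pair": np.repeat(postmeno_pair, 2),
        "er_positive_pair": np.repeat(er_pos_pair, 2),
    }, index=participants.index)

    return SyntheticStudy(
        study=study,
        truth=truth,
        cutpoints=cutpoints,
        overall_boundaries=(float(q33), float(q66)),
        config=config,
        seed=int(seed),
    )
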