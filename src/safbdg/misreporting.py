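"""Goldberg/Black plausibility screening of reported energy intake.

A subject's reported energy intake (EI) is compared with an estimated
basal metabolic rate (BMR) through the ratio EI/BMR. Under energy balance
this ratio should sit near the assumed physical activity level (PAL);
log-normal confidence limits around the PAL — built from within-subject
coefficients of variation for energy intake, BMR estimation and PAL —
define a plausible band. Ratios below the lower limit flag under-reporting,
above the upper limit over-reporting.

BMR is estimated from the Schofield age/sex-band equations (weight-only
form), which is an implementation choice: the motivating analysis cites the
principle without printing equations, and the Schofield coefficients are
the conventional companion of the Goldberg screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError

#: Schofield weight-only coefficients, MJ/d = a * weight_kg + b,
#: by sex and age band [lower, upper).
SCHOFIELD_COEFFICIENTS = {
    ("female", 18.0, 30.0): (0.062, 2.036),
    ("female", 30.0, 60.0): (0.034, 3.538),
    ("female", 60.0, math.inf): (0.038, 2.755),
    ("male", 18.0, 30.0): (0.063, 2.896),
    ("male", 30.0, 60.0): (0.048, 3.653),
    ("male", 60.0, math.inf): (0.049, 2.459),
}

STATUS_LEVELS = ("under", "plausible", "over")


@dataclass(frozen=True)
class GoldbergParams:
    """Assumptions behind the Goldberg confidence limits.

    Defaults: PAL 1.55 (sedentary reference); within-subject CVs of 23 %
    for energy intake, 8.5 % for BMR estimation and 15 % for PAL; a single
    observation per subject (``n_days = 1`` — one month-scope questionnaire
    treated as one measurement); 95 % limits (z = 1.96).
    """

    pal: float = 1.55
    cv_ei: float = 23.0      # % within-subject CV of reported energy
    cv_bmr: float = 8.5      # % CV of BMR estimation
    cv_pal: float = 15.0     # % CV of PAL
    n_days: int = 1
    z: float = 1.96

    @property
    def s_pct(self) -> float:
        """Combined CV (%) of the EI/BMR ratio around the PAL."""
        return math.sqrt(
            self.cv_ei ** 2 / self.n_days + self.cv_bmr ** 2
            + self.cv_pal ** 2
        )


DEFAULT_GOLDBERG = GoldbergParams()


def goldberg_limits(params: GoldbergParams = DEFAULT_GOLDBERG
                    ) -> tuple[float, float]:
    """Lower and upper plausibility limits on the EI/BMR ratio."""
    half_width = params.z * params.s_pct / 100.0
    return (params.pal * math.exp(-half_width),
            params.pal * math.exp(half_width))


def bmr_schofield(sex, age, weight_kg):
    """Schofield basal metabolic rate in kJ/d.

    Vectorised over ``age``/``weight_kg``; ``sex`` may be a scalar or an
    aligned array of ``"female"``/``"male"``. Ages below 18 are outside the
    supported bands.
    """
    age_arr = np.asarray(age, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    sex_arr = np.broadcast_to(
        np.asarray(sex, dtype=object), age_arr.shape or (1,)).ravel()
    age_flat = np.atleast_1d(age_arr).astype(float)
    weight_flat = np.broadcast_to(
        weight, age_arr.shape or (1,)).ravel().astype(float)

    if (weight_flat <= 0).any():
        raise DomainError("weight must be strictly positive")
    if (age_flat < 18).any():
        raise DomainError("Schofield adult bands require age >= 18")

    mj = np.empty_like(age_flat)
    mj.fill(np.nan)
    for (band_sex, lo, hi), (a, b) in SCHOFIELD_COEFFICIENTS.items():
        mask = (sex_arr == band_sex) & (age_flat >= lo) & (age_flat < hi)
        mj[mask] = a * weight_flat[mask] + b
    if np.isnan(mj).any():
        bad = sorted(set(sex_arr[np.isnan(mj)]))
        raise DomainError(f"unsupported sex value(s): {bad}")
    kj = mj * 1000.0
    return float(kj[0]) if np.isscalar(age) and np.isscalar(weight_kg) else \
        kj.reshape(age_arr.shape)


def goldberg_classify(energy_kj, bmr_kj,
                      params: GoldbergParams = DEFAULT_GOLDBERG):
    """Classify reported energy intake as under/plausible/over.

    Returns the status string for scalars, or an object array for arrays.
    """
    energy = np.asarray(energy_kj, dtype=float)
    bmr = np.asarray(bmr_kj, dtype=float)
    if (bmr <= 0).any():
        raise DomainError("BMR must be strictly positive")
    if (energy <= 0).any():
        raise DomainError("energy intake must be strictly positive")
    lower, upper = goldberg_limits(params)
    ratio = energy / bmr
    status = np.where(ratio < lower, "under",
                      np.where(ratio > upper, "over", "plausible"))
    if np.isscalar(energy_kj) and np.isscalar(bmr_kj):
        return str(status)
    return status


def classify_study(
    participants: pd.DataFrame,
    nutrients: pd.DataFrame,
    params: GoldbergParams = DEFAULT_GOLDBERG,
    sex: str = "female",
) -> pd.DataFrame:
    """Per-subject reporting status table (``bmr_kj``, ``ei_bmr_ratio``,
    ``reporting_status`` plus the limits used).

    ``sex`` applies to every subject unless the participants table carries
    its own ``sex`` column (the motivating study enrolled women only).
    """
    nutrients = nutrients.loc[participants.index]
    sexes = participants["sex"] if "sex" in participants.columns else sex
    bmr = bmr_schofield(
        np.asarray(sexes) if not np.isscalar(sexes) else sexes,
        participants["age"].to_numpy(dtype=float),
        participants["weight_kg"].to_numpy(dtype=float),
    )
    energy = nutrients["energy_kj"].to_numpy(dtype=float)
    lower, upper = goldberg_limits(params)
    out = pd.DataFrame(index=participants.index.copy())
    out["bmr_kj"] = bmr
    out["ei_bmr_ratio"] = energy / bmr
    out["reporting_status"] = goldberg_classify(energy, bmr, params)
    out["cutoff_lower"] = lower
    out["cutoff_upper"] = upper
    return out
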