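"""Aggregate item-level g/d intakes into guideline-relevant exposures.

Produces, per subject: grams per scored food family, starchy food-guide
units, grams per FAO dietary-diversity group, the 0-9 dietary diversity
score (DDS), and the percentage of total energy (%TE) contributed by total
fat, saturated fat and added sugar.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError, MappingError
from .io import FOOD_FAMILIES, GroupMapping

#: kJ per gram used for %TE conversion (Atwater-type factors in kJ).
KJ_PER_G_FAT = 37.0
KJ_PER_G_SUGAR = 17.0

#: A FAO group counts toward the DDS when its intake reaches this many g/d.
DDS_THRESHOLD_G = 15.0
LOW_DIVERSITY_DDS = 4

FAMILY_COLUMNS = {
    "fruit_veg": "fruitveg_g",
    "legume": "legume_g",
    "dairy_liquid": "dairy_liquid_g",
    "hard_cheese": "cheese_g",
    "fish_chicken_leanmeat": "fcl_meat_g",
    "egg": "egg_g",
}
FAO_COLUMNS = [f"fao{g}_g" for g in range(1, 10)]


def pct_total_energy(nutrient_g, kj_per_g: float, energy_kj):
    """Percentage of total energy supplied by ``nutrient_g`` grams/day.

    ``100 * nutrient_g * kj_per_g / energy_kj``; energy must be positive and
    the nutrient nonnegative.
    """
    nutrient = np.asarray(nutrient_g, dtype=float)
    energy = np.asarray(energy_kj, dtype=float)
    if (nutrient < 0).any():
        raise DomainError("nutrient grams must be nonnegative")
    if (energy <= 0).any():
        raise DomainError("energy_kj must be strictly positive")
    pct = 100.0 * nutrient * kj_per_g / energy
    return float(pct) if np.isscalar(nutrient_g) else pct


def compute_dds(fao_grams, threshold_g: float = DDS_THRESHOLD_G):
    """Dietary diversity score: number of FAO groups at >= ``threshold_g``.

    ``fao_grams`` is an (n, 9) array-like or DataFrame of group totals.
    Returns ``(dds, low_diversity)`` where ``low_diversity`` flags DDS < 4.
    """
    grams = np.asarray(fao_grams, dtype=float)
    one_row = grams.ndim == 1
    grams = np.atleast_2d(grams)
    if grams.shape[1] != 9:
        raise DomainError("expected totals for the nine FAO groups")
    dds = (grams >= threshold_g).sum(axis=1)
    low = dds < LOW_DIVERSITY_DDS
    if one_row:
        return int(dds[0]), bool(low[0])
    return dds, low


def aggregate_groups(
    intakes: pd.DataFrame,
    nutrients: pd.DataFrame,
    mapping: GroupMapping,
    dds_threshold_g: float = DDS_THRESHOLD_G,
) -> pd.DataFrame:
    """Build the per-subject exposure table used by both scoring schemes.

    Parameters
    ----------
    intakes
        Subjects x food items, g/d.
    nutrients
        Per-subject ``energy_kj``, ``fat_g``, ``sfa_g``, ``added_sugar_g``.
    mapping
        Food-group mapping; every intake column must be covered.

    Raises
    ------
    MappingError
        If any intake item is unmapped.
    DomainError
        If any subject has nonpositive energy intake.
    """
    missing = mapping.unmapped(intakes.columns)
    if missing:
        raise MappingError(
            "unmapped intake item(s): " + ", ".join(missing)
        )
    nutrients = nutrients.loc[intakes.index]
    if (nutrients["energy_kj"] <= 0).any():
        raise DomainError("energy_kj must be strictly positive")

    table = mapping.table.loc[list(intakes.columns)]
    values = intakes.to_numpy(dtype=float)

    out = pd.DataFrame(index=intakes.index.copy())
    fam = table["family"].to_numpy(dtype=object)
    for family, col in FAMILY_COLUMNS.items():
        out[col] = values[:, fam == family].sum(axis=1)

    starchy = fam == "starchy"
    unit_g = table["starchy_unit_g"].to_numpy(dtype=float)
    if starchy.any():
        out["starchy_units"] = (
            values[:, starchy] / unit_g[starchy]
        ).sum(axis=1)
    else:
        out["starchy_units"] = 0.0

    dds_codes = table["dds_group"].to_numpy(dtype=float)
    for g, col in enumerate(FAO_COLUMNS, start=1):
        out[col] = values[:, dds_codes == g].sum(axis=1)
    dds, low = compute_dds(out[FAO_COLUMNS], dds_threshold_g)
    out["dds"] = dds
    out["low_diversity"] = low

    energy = nutrients["energy_kj"].to_numpy(dtype=float)
    out["fat_pct_te"] = pct_total_energy(
        nutrients["fat_g"].to_numpy(dtype=float), KJ_PER_G_FAT, energy)
    out["sfa_pct_te"] = pct_total_energy(
        nutrients["sfa_g"].to_numpy(dtype=float), KJ_PER_G_FAT, energy)
    out["sugar_pct_te"] = pct_total_energy(
        nutrients["added_sugar_g"].to_numpy(dtype=float), KJ_PER_G_SUGAR,
        energy)
    return out
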