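"""Foliar Insecticide Impact (FII) index.

The FII is a bee-weighted variant of the Environmental Impact Quotient
(EIQ): for every foliar-applied insecticide active ingredient the index
multiplies a categorical bee-toxicity coefficient ``Z`` (5/3/1 by acute
contact LD50), the plant-surface half-life ``P = DT50 / 4`` (days), the
EIQ bee-exposure weighting of 3, and the regional application rate
``M / A`` (mass of active ingredient per hectare sprayed), then sums over
active ingredients within a region-year:

    FII_{R,y} = sum_ai 3 * Z_ai * P_ai * (M_{ai,R,y} / A_{R,y})

Regional scores are assigned to 5 km grid cells by the region holding the
majority of each cell's area.  Only the bee component of the EIQ is
computed; consumer/farm-worker/ecological terms are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PesticideProperties",
    "PesticideApplication",
    "FiiScore",
    "classify_toxicity",
    "plant_surface_half_life",
    "fii_contribution",
    "regional_fii",
    "assign_region_score_to_cells",
    "build_fii_panel",
]

#: EIQ weighting for bee exposure relative to other taxa (birds also 3,
#: beneficial arthropods 5); redundant as a common factor but retained for
#: comparability with published EIQ scores.
BEE_EXPOSURE_WEIGHT = 3.0


@dataclass(frozen=True)
class PesticideProperties:
    """Toxicity and degradation properties of one active ingredient."""

    active_ingredient: str
    ld50: float  # acute contact LD50, µg per bee
    dt50: float  # soil degradation half-life, days

    def __post_init__(self) -> None:
        if not np.isfinite(self.ld50) or self.ld50 <= 0:
            raise ValueError(
                f"ld50 must be positive for {self.active_ingredient!r}, got {self.ld50}"
            )
        if not np.isfinite(self.dt50) or self.dt50 <= 0:
            raise ValueError(
                f"dt50 must be positive for {self.active_ingredient!r}, got {self.dt50}"
            )


@dataclass(frozen=True)
class PesticideApplication:
    """One usage record: mass applied and area sprayed in a region-year."""

    active_ingredient: str
    region: str
    year: int
    mass_applied: float  # kg of active ingredient
    area_sprayed: float  # ha of crop sprayed

    def __post_init__(self) -> None:
        if self.mass_applied < 0:
            raise ValueError(f"mass_applied must be >= 0, got {self.mass_applied}")
        if self.area_sprayed <= 0:
            raise ValueError(f"area_sprayed must be > 0, got {self.area_sprayed}")


@dataclass(frozen=True)
class FiiScore:
    region: str
    year: int
    value: float


def classify_toxicity(ld50: float, *, boundary_class: int = 3) -> int:
    """Map an LD50 (µg/bee) to the EIQ bee-toxicity coefficient Z.

    High-toxicity compounds (LD50 < 1) score 5, medium (1–100) score 3
    and low (LD50 > 100) score 1.  Values exactly on a bracket boundary
    (1 or 100) fall in the middle class by default; ``boundary_class``
    overrides that convention.
    """
    if ld50 is None or not np.isfinite(ld50) or ld50 <= 0:
        raise ValueError(f"ld50 must be a positive number, got {ld50}")
    if ld50 < 1:
        return 5
    if ld50 > 100:
        return 1
    if ld50 in (1, 100):
        return boundary_class
    return 3


def plant_surface_half_life(dt50: float) -> float:
    """Plant-surface half-life P (days), estimated as DT50 / 4."""
    if dt50 is None or not np.isfinite(dt50) or dt50 <= 0:
        raise ValueError(f"dt50 must be a positive number, got {dt50}")
    return dt50 / 4.0


def fii_contribution(
    app: PesticideApplication, props: PesticideProperties
) -> float:
    """FII contribution of one application: 3 * Z * P * (M / A)."""
    if app.active_ingredient != props.active_ingredient:
        raise ValueError(
            "active-ingredient mismatch: application is for "
            f"{app.active_ingredient!r} but properties are for "
            f"{props.active_ingredient!r}"
        )
    z = classify_toxicity(props.ld50)
    p = plant_surface_half_life(props.dt50)
    return BEE_EXPOSURE_WEIGHT * z * p * (app.mass_applied / app.area_sprayed)


def regional_fii(
    apps: list[PesticideApplication],
    props_table: dict[str, PesticideProperties],
) -> FiiScore:
    """Sum FII contributions over active ingredients in one region-year.

    Duplicate rows for an ingredient are treated as separate applications
    and their contributions add.  An empty list scores 0 (the region-year
    saw no foliar insecticide).
    """
    if not apps:
        raise ValueError("cannot infer region/year from an empty application list")
    region, year = apps[0].region, apps[0].year
    for app in apps:
        if (app.region, app.year) != (region, year):
            raise ValueError(
                f"applications mix region-years: {(app.region, app.year)} vs "
                f"{(region, year)}"
            )
    missing = sorted(
        {a.active_ingredient for a in apps} - set(props_table)
    )
    if missing:
        raise KeyError(
            f"no pesticide properties for active ingredient(s): {missing}"
        )
    total = sum(fii_contribution(a, props_table[a.active_ingredient]) for a in apps)
    return FiiScore(region=region, year=year, value=total)


def assign_region_score_to_cells(
    scores: pd.DataFrame, cell_region_map: pd.DataFrame
) -> pd.DataFrame:
    """Assign each 5 km cell the FII of its majority region, per year.

    Parameters
    ----------
    scores
        Columns ``region, year, fii``.
    cell_region_map
        Columns ``cell5km_id, region`` and optionally ``area_fraction``;
        when fractions are given the region with the largest fraction wins.

    Returns
    -------
    DataFrame with columns ``cell5km_id, year, fii`` (one row per
    cell-year present in ``scores``'s year range).
    """
    cmap = cell_region_map.copy()
    if "area_fraction" in cmap.columns:
        cmap = (
            cmap.sort_values("area_fraction", ascending=False)
            .drop_duplicates("cell5km_id", keep="first")
        )
    else:
        dup = cmap["cell5km_id"].duplicated()
        if dup.any():
            bad = sorted(cmap.loc[dup, "cell5km_id"].unique())
            raise ValueError(
                f"cells mapped to more than one region without area fractions: {bad}"
            )
    cmap = cmap[["cell5km_id", "region"]]
    merged = cmap.merge(scores[["region", "year", "fii"]], on="region", how="left")
    unmapped = merged.loc[merged["year"].isna(), "cell5km_id"].unique()
    if len(unmapped):
        raise ValueError(
            "cells whose region has no FII scores: " + ", ".join(map(str, unmapped))
        )
    return merged[["cell5km_id", "year", "fii"]].sort_values(
        ["cell5km_id", "year"], ignore_index=True
    )


def build_fii_panel(
    usage: pd.DataFrame,
    properties: pd.DataFrame,
    cell_regions: pd.DataFrame,
) -> pd.DataFrame:
    """Compute the per-cell annual FII panel from the three input tables.

    ``usage`` has columns ``region, year, active_ingredient,
    mass_applied_kg, area_sprayed_ha``; ``properties`` has
    ``active_ingredient, ld50_ug_per_bee, dt50_days``.  Region-years with
    no usage rows are absent from the output (callers decide whether
    absence means zero or un-surveyed; the synthetic pipeline emits
    explicit zero-mass rows).
    """
    props = {
        str(r.active_ingredient): PesticideProperties(
            str(r.active_ingredient), float(r.ld50_ug_per_bee), float(r.dt50_days)
        )
        for r in properties.itertuples(index=False)
    }
    rows = []
    for (region, year), grp in usage.groupby(["region", "year"], sort=True):
        apps = [
            PesticideApplication(
                str(r.active_ingredient),
                str(region),
                int(year),
                float(r.mass_applied_kg),
                float(r.area_sprayed_ha),
            )
            for r in grp.itertuples(index=False)
        ]
        score = regional_fii(apps, props)
        rows.append({"region": score.region, "year": score.year, "fii": score.value})
    scores = pd.DataFrame(rows)
    return assign_region_score_to_cells(scores, cell_regions)
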