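"""Per-cell annual covariate panel: crop cover, neonicotinoid exposure, FII.

Crop cover and pesticide-usage surveys run on alternate years; interior
gap years are filled by the arithmetic mean of the two flanking surveys
before any product is formed.  Neonicotinoid exposure for a 5 km cell is
the area of oilseed rape in the cell times the proportion of the crop
treated with neonicotinoid seed dressings in the cell's region that year.
Covariates are centred (not scaled) on their grand mean over all modelled
cell-years; the means are stored so counterfactual scenarios can be built
on the same scale the model was fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariatePanel",
    "interpolate_biennial",
    "neonic_exposure",
    "center_covariates",
    "build_covariate_panel",
]

COVARIATE_COLUMNS = ("osr", "neonic", "fii")


@dataclass
class CovariatePanel:
    """Long-form cell-year covariates plus stored centring means.

    ``table`` has one row per (cell5km_id, year) with raw columns
    ``osr, neonic, fii`` and centred columns ``osr_c, neonic_c, fii_c``;
    ``means`` maps raw column name to the grand mean subtracted.
    """

    table: pd.DataFrame
    means: dict[str, float] = field(default_factory=dict)

    @property
    def cells(self) -> np.ndarray:
        return np.sort(self.table["cell5km_id"].unique())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def to_arrays(
        self, cells: np.ndarray | None = None, years: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Centred covariates as dense (n_cells, n_years) arrays."""
        cells = self.cells if cells is None else np.asarray(cells)
        years = self.years if years is None else np.asarray(years)
        wide = {}
        piv = self.table.pivot(index="cell5km_id", columns="year")
        for col in COVARIATE_COLUMNS:
            block = piv[col + "_c"].reindex(index=cells, columns=years)
            if block.isna().any().any():
                missing = int(block.isna().sum().sum())
                raise ValueError(
                    f"covariate panel incomplete: {missing} missing cell-years for {col}"
                )
            wide[col] = block.to_numpy(dtype=float)
        return wide


def interpolate_biennial(series: dict[int, float]) -> dict[int, float]:
    """Fill interior gap years of a biennial series with flanking means.

    A year ``y`` absent from ``series`` but with both ``y-1`` and ``y+1``
    present gets ``(series[y-1] + series[y+1]) / 2``.  Observed years are
    returned unchanged; leading/trailing years stay missing.  A gap wider
    than one year raises, because the survey design guarantees at most
    alternate-year gaps.
    """
    if not series:
        return {}
    years = sorted(series)
    out = dict(series)
    for a, b in zip(years[:-1], years[1:]):
        gap = b - a
        if gap == 1:
            continue
        if gap == 2:
            out[a + 1] = (series[a] + series[b]) / 2.0
        else:
            raise ValueError(
                f"gap of {gap} years between observations {a} and {b}; "
                "only alternate-year gaps can be interpolated"
            )
    return dict(sorted(out.items()))


def neonic_exposure(osr_area: float, proportion_treated: float) -> float:
    """Exposure (ha of treated crop) = crop area x proportion treated."""
    if not 0.0 <= proportion_treated <= 1.0:
        raise ValueError(
            f"proportion_treated must lie in [0, 1], got {proportion_treated}"
        )
    if osr_area < 0:
        raise ValueError(f"osr_area must be >= 0, got {osr_area}")
    return osr_area * proportion_treated


def center_covariates(
    panel: pd.DataFrame, columns: tuple[str, ...] = COVARIATE_COLUMNS
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Centre each covariate column on its grand mean over all rows.

    Returns the panel with added ``<col>_c`` columns and the dict of
    subtracted means (needed to build counterfactual covariates on the
    fitted scale).
    """
    out = panel.copy()
    means: dict[str, float] = {}
    for col in columns:
        if out[col].isna().any():
            n = int(out[col].isna().sum())
            raise ValueError(f"column {col!r} has {n} missing values; panel must be complete")
        mu = float(out[col].mean())
        means[col] = mu
        out[col + "_c"] = out[col] - mu
    return out, means


def _interpolate_table(
    table: pd.DataFrame, key_cols: list[str], value_col: str
) -> pd.DataFrame:
    """Apply biennial interpolation within each group of key_cols."""
    frames = []
    for keys, grp in table.groupby(key_cols, sort=True):
        series = dict(zip(grp["year"].astype(int), grp[value_col].astype(float)))
        filled = interpolate_biennial(series)
        frame = pd.DataFrame(
            {"year": list(filled), value_col: list(filled.values())}
        )
        if not isinstance(keys, tuple):
            keys = (keys,)
        for k, v in zip(key_cols, keys):
            frame[k] = v
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[key_cols + ["year", value_col]]


def build_covariate_panel(
    osr_table: pd.DataFrame,
    treated_table: pd.DataFrame,
    fii_panel: pd.DataFrame,
    cell_region_map: pd.DataFrame,
    years: tuple[int, int] | None = None,
    osr_scale: float = 1.0,
) -> CovariatePanel:
    """Assemble the centred covariate panel for all modelled cell-years.

    Parameters
    ----------
    osr_table
        ``cell5km_id, year, osr_ha`` — possibly biennial.
    treated_table
        ``region, year, proportion_treated`` — possibly biennial.
    fii_panel
        ``cell5km_id, year, fii`` from :func:`beepersist.fii.build_fii_panel`
        — possibly biennial (regional scores are interpolated upstream of
        cell assignment or here; both orders give identical values since
        assignment is a lookup).
    cell_region_map
        ``cell5km_id, region`` (+ optional ``area_fraction``).
    years
        Optional (first, last) inclusive range to restrict the panel to.
    osr_scale
        Unit conversion applied to ``osr_ha`` before the exposure product
        (e.g. 1e-3 expresses cover and exposure in thousands of hectares,
        the scale on which coefficients of order one are interpretable).
    """
    osr = _interpolate_table(osr_table, ["cell5km_id"], "osr_ha")
    treated = _interpolate_table(treated_table, ["region"], "proportion_treated")
    fii = _interpolate_table(fii_panel, ["cell5km_id"], "fii")

    cmap = cell_region_map.copy()
    if "area_fraction" in cmap.columns:
        cmap = cmap.sort_values("area_fraction", ascending=False).drop_duplicates(
            "cell5km_id", keep="first"
        )
    cmap = cmap[["cell5km_id", "region"]]

    panel = osr.merge(cmap, on="cell5km_id", how="left")
    if panel["region"].isna().any():
        bad = sorted(panel.loc[panel["region"].isna(), "cell5km_id"].unique())
        raise ValueError(f"cells with no region mapping: {bad}")
    panel = panel.merge(treated, on=["region", "year"], how="left")
    # Years before the first treated-proportion observation are untreated.
    first_obs = treated.groupby("region")["year"].min().rename("first_treat_year")
    panel = panel.merge(first_obs, on="region", how="left")
    pre = panel["year"] < panel["first_treat_year"]
    panel.loc[pre & panel["proportion_treated"].isna(), "proportion_treated"] = 0.0
    panel = panel.merge(fii, on=["cell5km_id", "year"], how="left")

    if years is not None:
        lo, hi = years
        panel = panel[(panel["year"] >= lo) & (panel["year"] <= hi)]

    for col, label in [
        ("osr_ha", "oilseed-rape cover"),
        ("proportion_treated", "treated proportion"),
        ("fii", "FII"),
    ]:
        if panel[col].isna().any():
            miss = panel.loc[panel[col].isna(), ["cell5km_id", "year"]]
            raise ValueError(
                f"{label} missing for {len(miss)} cell-years, e.g. "
                f"{miss.head(3).to_dict('records')}"
            )

    panel = panel.rename(columns={"osr_ha": "osr"})
    panel["osr"] = panel["osr"] * osr_scale
    panel["neonic"] = [
        neonic_exposure(o, p)
        for o, p in zip(panel["osr"], panel["proportion_treated"])
    ]
    panel = panel[["cell5km_id", "year", "osr", "neonic", "fii"]].sort_values(
        ["cell5km_id", "year"], ignore_index=True
    )
    centred, means = center_covariates(panel)
    return CovariatePanel(table=centred, means=means)
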