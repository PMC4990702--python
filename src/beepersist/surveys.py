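"""Assemble volunteer occurrence records into an occupancy detection dataset.

A *survey* (visit) is a unique combination of calendar date and 1 km grid
cell; the species recorded on it form a list whose length proxies
recording effort.  Visits are categorised as single-species (length 1),
short (2–3) or long (>3) lists; the two binary indicators ``is_short``
and ``is_long`` enter the detection sub-model.  Occupancy itself is
modelled at the 5 km scale, so visits from 1 km cells pool under their
parent 5 km cell.

Filtering rules mirror common practice for opportunistic recording-scheme
data: keep 1 km cells surveyed in at least two distinct years, collapse
species that recorders cannot reliably separate into aggregates, and
retain only species recorded on a minimum number of surveys.  Detections
of non-retained species still count toward list length — the list
measures effort, not the modelled community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyData",
    "DetectionDataset",
    "build_surveys",
    "filter_cells",
    "aggregate_species",
    "filter_species",
    "assemble_detection_dataset",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("single", "short", "long")


@dataclass
class SurveyData:
    """Visit-level survey data.

    ``visits`` has one row per visit: ``visit_id, cell1km_id, cell5km_id,
    date, year, list_length, is_short, is_long``.  ``detections`` is long
    form: ``visit_id, species``.
    """

    visits: pd.DataFrame
    detections: pd.DataFrame

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def species_survey_counts(self) -> pd.Series:
        """Number of distinct visits on which each species was recorded."""
        return self.detections.groupby("species")["visit_id"].nunique()


@dataclass
class DetectionDataset:
    """Sufficient statistics of the detection data for the occupancy model.

    Because detection probability depends on the visit only through its
    list category and year, the data reduce without loss to per
    (site, year, category) visit counts and per (species, site, year,
    category) detection counts.

    Attributes
    ----------
    species : list of retained species ids (index i)
    forager : bool array (n_species,), oilseed-rape forager flag
    sites : list of 5 km cell ids (index j)
    years : int array of modelled years (index t), contiguous
    visit_counts : int array (n_sites, n_years, 3) — visits per category
    det_counts : int array (n_species, n_sites, n_years, 3)
    """

    species: list[str]
    forager: np.ndarray
    sites: list[str]
    years: np.ndarray
    visit_counts: np.ndarray
    det_counts: np.ndarray
    visits: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def any_detection(self) -> np.ndarray:
        """Bool (n_species, n_sites, n_years): species detected that site-year."""
        return self.det_counts.sum(axis=3) > 0

    def surveyed(self) -> np.ndarray:
        """Bool (n_sites, n_years): site-year received at least one visit."""
        return self.visit_counts.sum(axis=2) > 0

    def summary(self) -> dict:
        surveyed = self.surveyed()
        return {
            "n_species": self.n_species,
            "n_forager": int(self.forager.sum()),
            "n_sites": self.n_sites,
            "n_years": self.n_years,
            "n_visits": int(self.visit_counts.sum()),
            "n_detections": int(self.det_counts.sum()),
            "prop_siteyears_surveyed": float(surveyed.mean()),
            "prop_single_lists": float(
                self.visit_counts[:, :, 0].sum() / max(1, self.visit_counts.sum())
            ),
        }

    def to_long(self) -> pd.DataFrame:
        """Long-form serialisation: one row per species-site-year-category."""
        i, j, t, c = np.nonzero(np.ones_like(self.det_counts))
        return pd.DataFrame(
            {
                "species": np.asarray(self.species)[i],
                "cell5km_id": np.asarray(self.sites)[j],
                "year": self.years[t],
                "category": np.asarray(CATEGORIES)[c],
                "n_visits": self.visit_counts[j, t, c],
                "n_detections": self.det_counts[i, j, t, c],
            }
        )


def _categorise(list_length: pd.Series) -> pd.DataFrame:
    is_short = list_length.isin((2, 3)).astype(int)
    is_long = (list_length > 3).astype(int)
    return pd.DataFrame({"is_short": is_short, "is_long": is_long})


def build_surveys(
    records: pd.DataFrame, cell_lookup: pd.DataFrame | None = None
) -> SurveyData:
    """Group occurrence records into visits (unique date × 1 km cell).

    ``records`` needs columns ``species, date, cell1km_id``; ``date`` is
    ISO-8601.  Records with unparseable dates or missing cell ids lack
    the survey's spatio-temporal resolution and are excluded (count
    logged).  ``cell_lookup`` maps ``cell1km_id`` to ``cell5km_id``; when
    omitted, ids of the form ``<cell5km>_<suffix>`` are split on the last
    underscore.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"], format="%Y-%m-%d", errors="coerce")
    bad = rec["date"].isna() | rec["cell1km_id"].isna() | rec["species"].isna()
    if bad.any():
        logger.info("excluded %d records with coarse/invalid resolution", int(bad.sum()))
        rec = rec[~bad]
    rec = rec.drop_duplicates(["species", "date", "cell1km_id"])

    visit_keys = rec[["date", "cell1km_id"]].drop_duplicates().reset_index(drop=True)
    visit_keys = visit_keys.sort_values(["date", "cell1km_id"], ignore_index=True)
    visit_keys["visit_id"] = np.arange(len(visit_keys))
    rec = rec.merge(visit_keys, on=["date", "cell1km_id"])

    visits = visit_keys.copy()
    visits["year"] = visits["date"].dt.year
    if cell_lookup is not None:
        visits = visits.merge(cell_lookup[["cell1km_id", "cell5km_id"]], on="cell1km_id", how="left")
        if visits["cell5km_id"].isna().any():
            bad_ids = sorted(visits.loc[visits["cell5km_id"].isna(), "cell1km_id"].unique())
            raise ValueError(f"1 km cells missing from cell_lookup: {bad_ids[:10]}")
    else:
        visits["cell5km_id"] = visits["cell1km_id"].str.rsplit("_", n=1).str[0]

    detections = rec[["visit_id", "species"]].reset_index(drop=True)
    lengths = detections.groupby("visit_id")["species"].nunique()
    visits["list_length"] = visits["visit_id"].map(lengths).astype(int)
    visits[["is_short", "is_long"]] = _categorise(visits["list_length"])
    visits = visits[
        ["visit_id", "cell1km_id", "cell5km_id", "date", "year",
         "list_length", "is_short", "is_long"]
    ]
    return SurveyData(visits=visits, detections=detections)


def filter_cells(sdata: SurveyData, min_years: int = 2) -> SurveyData:
    """Keep visits from 1 km cells surveyed in >= ``min_years`` distinct years."""
    years_per_cell = sdata.visits.groupby("cell1km_id")["year"].nunique()
    keep_cells = years_per_cell[years_per_cell >= min_years].index
    visits = sdata.visits[sdata.visits["cell1km_id"].isin(keep_cells)].reset_index(drop=True)
    detections = sdata.detections[
        sdata.detections["visit_id"].isin(visits["visit_id"])
    ].reset_index(drop=True)
    if visits.empty:
        logger.warning("cell filter (min_years=%d) removed every visit", min_years)
    return SurveyData(visits=visits, detections=detections)


def aggregate_species(
    sdata: SurveyData, aggregates: dict[str, str] | pd.DataFrame | None
) -> SurveyData:
    """Rename members of species aggregates and collapse duplicate detections.

    ``aggregates`` maps member species to aggregate id (e.g. both
    *Bombus terrestris* and *B. lucorum* to one "terrestris/lucorum"
    aggregate, whose workers recorders cannot separate); either a dict or
    a table with columns ``species, aggregate``.  List lengths are
    recomputed, since two members on one visit collapse to one entry.
    """
    if aggregates is None or len(aggregates) == 0:
        return sdata
    if isinstance(aggregates, pd.DataFrame):
        dup = aggregates.groupby("species")["aggregate"].nunique()
        multi = sorted(dup[dup > 1].index)
        if multi:
            raise ValueError(
                f"species mapped to more than one aggregate: {multi}"
            )
        mapping = dict(zip(aggregates["species"], aggregates["aggregate"]))
    else:
        mapping = dict(aggregates)
    detections = sdata.detections.copy()
    detections["species"] = detections["species"].map(lambda s: mapping.get(s, s))
    detections = detections.drop_duplicates(["visit_id", "species"]).reset_index(drop=True)
    visits = sdata.visits.copy()
    lengths = detections.groupby("visit_id")["species"].nunique()
    visits["list_length"] = visits["visit_id"].map(lengths).astype(int)
    visits[["is_short", "is_long"]] = _categorise(visits["list_length"])
    return SurveyData(visits=visits, detections=detections)


def filter_species(sdata: SurveyData, min_surveys: int = 500) -> list[str]:
    """Species recorded on >= ``min_surveys`` visits, after aggregation.

    Returns the retained species list only; the survey data are left
    untouched so that non-retained species keep contributing to list
    length (they were real recording effort).
    """
    counts = sdata.species_survey_counts()
    return sorted(counts[counts >= min_surveys].index)


def assemble_detection_dataset(
    sdata: SurveyData,
    species_traits: pd.DataFrame,
    retained_species: list[str] | None = None,
    years: tuple[int, int] | None = None,
) -> DetectionDataset:
    """Build the model's detection tensor at 5 km resolution.

    ``species_traits`` has columns ``species, osr_forager``; every
    retained species must appear in it.  ``years`` optionally fixes the
    modelled year range; by default it spans the first to last surveyed
    year, so interior unsurveyed site-years are explicit (their occupancy
    is imputed by the model).
    """
    if retained_species is None:
        retained_species = sorted(sdata.detections["species"].unique())
    traits = species_traits.set_index("species")["osr_forager"]
    missing = [s for s in retained_species if s not in traits.index]
    if missing:
        raise ValueError(f"species missing a forager flag: {missing}")
    forager = traits.loc[retained_species].to_numpy(dtype=bool)

    visits = sdata.visits
    if years is None:
        years_arr = np.arange(visits["year"].min(), visits["year"].max() + 1)
    else:
        years_arr = np.arange(years[0], years[1] + 1)
    sites = sorted(visits["cell5km_id"].unique())

    s_index = {s: i for i, s in enumerate(retained_species)}
    j_index = {s: j for j, s in enumerate(sites)}
    t_index = {int(y): t for t, y in enumerate(years_arr)}

    v = visits.copy()
    v["cat"] = np.where(v["is_long"] == 1, 2, np.where(v["is_short"] == 1, 1, 0))
    v["j"] = v["cell5km_id"].map(j_index)
    v["t"] = v["year"].map(t_index)
    if v["t"].isna().any():
        raise ValueError("visits outside the modelled year range")

    visit_counts = np.zeros((len(sites), len(years_arr), 3), dtype=np.int64)
    np.add.at(visit_counts, (v["j"].to_numpy(int), v["t"].to_numpy(int), v["cat"].to_numpy(int)), 1)

    det = sdata.detections.merge(v[["visit_id", "j", "t", "cat"]], on="visit_id")
    det = det[det["species"].isin(s_index)]
    det_counts = np.zeros((len(retained_species), len(sites), len(years_arr), 3), dtype=np.int64)
    np.add.at(
        det_counts,
        (
            det["species"].map(s_index).to_numpy(int),
            det["j"].to_numpy(int),
            det["t"].to_numpy(int),
            det["cat"].to_numpy(int),
        ),
        1,
    )
    return DetectionDataset(
        species=list(retained_species),
        forager=forager,
        sites=list(sites),
        years=years_arr,
        visit_counts=visit_counts,
        det_counts=det_counts,
        visits=v[["visit_id", "cell1km_id", "cell5km_id", "year", "list_length", "is_short", "is_long"]],
    )
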