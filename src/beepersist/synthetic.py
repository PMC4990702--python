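"""Synthetic study generator with known truth.

Emulates every input table of the wild-bee persistence analysis — a
nested 1 km/5 km landscape partitioned into regions, biennial crop-cover
and seed-treatment surveys, a foliar pesticide-usage table with
properties, species traits, and volunteer occurrence records — together
with the latent occupancy states and parameters that generated them, so
the whole pipeline can be exercised and parameter recovery tested
without any external data.

The generative model is the fitted model itself: species-level
parameters are drawn from the hierarchical group distributions, true
occupancy evolves by the colonisation/persistence dynamics on the
centred covariates, and detections are Bernoulli given presence.  The
default truth hyper-means for the persistence covariates are the
group-level effects the analysis is designed to estimate (neonicotinoid
exposure: forager −1.37, non-forager −0.46; crop cover: 1.06, −0.09;
foliar index: −0.017, −0.013), so recovery runs target those values.

Volunteer effort is heterogeneous: each 1 km cell has its own visit
rate, cell-years are inactive with some probability, and every visit
draws a latent effort class (single / short / long list).  Detections of
modelled species are drawn conditionally on the class covariates, and
background ("filler") species pad the list to the class's length, so
roughly half of all realised surveys are single-species lists.  Because
modelled detections can overflow the class band, the dataset's list
covariates are recomputed from the realised lists — the same rule the
survey-assembly module applies — which keeps the pipeline round-trip
exact at the cost of a small, documented approximation in the detection
covariate.

Crop cover and exposure enter the model in thousands of hectares per
5 km cell so that coefficients of order one correspond to realistic
effects; the emitted CSVs carry plain hectares.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import CovariatePanel, build_covariate_panel
from .fii import build_fii_panel
from .likelihood import inv_logit
from .surveys import DetectionDataset

__all__ = [
    "SimConfig",
    "TrueParams",
    "SimulationTruth",
    "SyntheticStudy",
    "simulate_landscape",
    "simulate_covariates",
    "simulate_params",
    "simulate_dynamics",
    "simulate_visits",
    "simulate_study",
]

#: model-scale factor for crop areas: hectares -> thousands of hectares
OSR_MODEL_SCALE = 1e-3


@dataclass
class SimConfig:
    """Study conditions of the synthetic data.

    Group-order tuples are (forager, nonforager).  Scale defaults (35
    species, 150 sites, 18 years) keep a full fit on one CPU within a
    desk-scale budget.
    """

    n_forager: int = 20
    n_nonforager: int = 15
    n_sites: int = 150
    cells_per_site: int = 5
    n_regions: int = 8
    first_year: int = 1994
    last_year: int = 2011
    first_treatment_year: int = 2002

    # truth hyper-parameters for persistence covariate effects
    mu_beta1: tuple[float, float] = (1.06, -0.09)
    mu_beta2: tuple[float, float] = (-1.37, -0.46)
    mu_beta3: tuple[float, float] = (-0.017, -0.013)
    sd_beta1: tuple[float, float] = (0.25, 0.25)
    sd_beta2: tuple[float, float] = (0.25, 0.25)
    sd_beta3: tuple[float, float] = (0.01, 0.01)
    # global species-effect distributions
    mu_gamma: float = -2.2
    sd_gamma: float = 0.4
    mu_beta0: float = 1.2
    sd_beta0: float = 0.4
    mu_beta4: float = -3.2
    sd_beta4: float = 0.4
    mu_beta5: float = 1.1
    sd_beta5: float = 0.25
    mu_beta6: float = 2.2
    sd_beta6: float = 0.25
    psi0_beta: tuple[float, float] = (5.0, 6.0)
    sigma_alpha: float = 0.25

    # neonicotinoid adoption ramp (proportion of crop treated)
    prop_treated_start: float = 0.374
    prop_treated_end: float = 0.830
    regional_prop_jitter: float = 0.04
    n_trial_regions: int = 0
    trial_proportion: float = 0.02

    # foliar-usage heterogeneity: persistent regional spread vs annual drift
    fii_regional_sd: float = 0.35
    fii_temporal_sd: float = 0.04

    # oilseed-rape cover per 5 km cell (fractions of the 2,500 ha cell)
    osr_beta: tuple[float, float] = (1.5, 2.2)
    osr_scale_ha: float = 1600.0
    osr_trend: float = 0.015
    osr_noise: float = 0.05

    # volunteer effort
    visit_rate_shape: float = 1.3
    visit_rate_mean: float = 1.6
    p_cellyear_inactive: float = 0.25
    list_class_probs: tuple[float, float, float] = (0.55, 0.27, 0.18)
    n_filler_species: int = 120

    @property
    def n_species(self) -> int:
        return self.n_forager + self.n_nonforager

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def survey_years(self) -> np.ndarray:
        """Biennial (even) years on which the crop/pesticide surveys run."""
        first_even = self.first_year + (self.first_year % 2)
        return np.arange(first_even, self.last_year, 2)


@dataclass
class TrueParams:
    """Generating parameters: per-species theta rows plus year effects."""

    species: list[str]
    group: np.ndarray  # 0 = forager, 1 = non-forager
    theta: np.ndarray  # (S, 9): lgamma, beta0..beta6, lpsi0
    alpha: np.ndarray  # (T,)
    hyper_mu: dict[str, float]
    hyper_sd: dict[str, float]

    @property
    def forager(self) -> np.ndarray:
        return self.group == 0


@dataclass
class SimulationTruth:
    params: TrueParams
    z: np.ndarray  # (S, J, T) latent occupancy
    panel: CovariatePanel
    config: SimConfig
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config": asdict(self.config),
            "species": self.params.species,
            "group": self.params.group.tolist(),
            "theta": self.params.theta.tolist(),
            "alpha": self.params.alpha.tolist(),
            "hyper_mu": self.params.hyper_mu,
            "hyper_sd": self.params.hyper_sd,
            "covariate_means": self.panel.means,
            "occupancy_by_species_year": self.z.mean(axis=1).tolist(),
        }
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticStudy:
    """All emitted tables plus the generating truth and direct dataset."""

    tables: dict[str, pd.DataFrame]
    truth: SimulationTruth
    dataset: DetectionDataset

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "truth.json").write_text(self.truth.to_json())


def simulate_landscape(config: SimConfig):
    """Deterministic nested landscape: sites, 1 km cells, regions."""
    if config.n_sites <= 0:
        raise ValueError("n_sites must be positive")
    sites = [f"S{k:03d}" for k in range(config.n_sites)]
    cell_lookup = pd.DataFrame(
        [
            {"cell1km_id": f"{s}_{c}", "cell5km_id": s}
            for s in sites
            for c in range(config.cells_per_site)
        ]
    )
    region_of_site = {
        s: f"R{(k * config.n_regions) // config.n_sites + 1}"
        for k, s in enumerate(sites)
    }
    cell_regions = pd.DataFrame(
        {
            "cell5km_id": sites,
            "region": [region_of_site[s] for s in sites],
            "area_fraction": 1.0,
        }
    )
    return sites, cell_lookup, cell_regions


def _logit(p):
    return np.log(p) - np.log1p(-p)


def simulate_covariates(config: SimConfig, rng: np.random.Generator, sites, cell_regions):
    """Biennial crop-cover, seed-treatment and pesticide-usage tables."""
    years = config.survey_years
    base = rng.beta(*config.osr_beta, size=len(sites)) * config.osr_scale_ha
    rows = []
    for y in years:
        drift = (1.0 + config.osr_trend) ** (y - config.first_year)
        noise = np.exp(rng.normal(0.0, config.osr_noise, size=len(sites)))
        osr = np.clip(base * drift * noise, 0.0, 2500.0)
        for s, v in zip(sites, osr):
            rows.append({"cell5km_id": s, "year": int(y), "osr_ha": float(v)})
    osr_cover = pd.DataFrame(rows)

    regions = sorted(cell_regions["region"].unique())
    trial_regions = set(regions[: config.n_trial_regions])
    l0 = _logit(config.prop_treated_start)
    l1 = _logit(config.prop_treated_end)
    span = 2011 - config.first_treatment_year
    rows = []
    for y in years:
        for r in regions:
            if y >= config.first_treatment_year:
                lg = l0 + (l1 - l0) * (y - config.first_treatment_year) / span
                p = inv_logit(lg + rng.normal(0.0, config.regional_prop_jitter))
            elif r in trial_regions and 1999 <= y <= 2001:
                p = config.trial_proportion
            else:
                p = 0.0
            rows.append(
                {"region": r, "year": int(y), "proportion_treated": float(p)}
            )
    neonic_treated = pd.DataFrame(rows)

    properties = pd.DataFrame(
        {
            "active_ingredient": [
                "pyrethroid_a", "pyrethroid_b", "carbamate_c",
                "organophosphate_d", "fungicide_like_e", "low_tox_f",
            ],
            "ld50_ug_per_bee": [0.05, 0.30, 8.0, 45.0, 150.0, 500.0],
            "dt50_days": [60.0, 20.0, 30.0, 10.0, 40.0, 8.0],
        }
    )
    region_osr = (
        osr_cover.merge(cell_regions[["cell5km_id", "region"]], on="cell5km_id")
        .groupby(["region", "year"])["osr_ha"].sum()
    )
    ingredients = list(properties["active_ingredient"])
    rates = {ai: rng.uniform(0.02, 0.10) for ai in ingredients}
    frac = {ai: rng.uniform(0.35, 0.85) for ai in ingredients}
    # persistent regional differences in usage intensity (spray pressure
    # varies between regions far more than it drifts between years)
    region_mult = {
        (ai, r): rng.lognormal(0.0, config.fii_regional_sd)
        for ai in ingredients
        for r in regions
    }
    drift = {ai: 1.0 for ai in ingredients}
    walk: dict[tuple[str, int], float] = {}
    for y in years:
        for ai in ingredients:
            drift[ai] *= np.exp(rng.normal(0.0, config.fii_temporal_sd))
            walk[(ai, int(y))] = drift[ai]
    rows = []
    for (r, y), total in region_osr.items():
        for ai in ingredients:
            area = max(total * frac[ai] * np.exp(rng.normal(0, 0.05)), 1.0)
            rate = rates[ai] * region_mult[(ai, r)] * walk[(ai, int(y))]
            mass = area * rate * np.exp(rng.normal(0, 0.03))
            rows.append(
                {
                    "region": r, "year": int(y), "active_ingredient": ai,
                    "mass_applied_kg": float(mass), "area_sprayed_ha": float(area),
                }
            )
    pesticide_usage = pd.DataFrame(rows)
    return osr_cover, neonic_treated, pesticide_usage, properties


def simulate_params(config: SimConfig, rng: np.random.Generator) -> TrueParams:
    """Draw species-level parameters from the truth hyper-distributions."""
    S = config.n_species
    species = [f"sp_f{k:02d}" for k in range(config.n_forager)] + [
        f"sp_n{k:02d}" for k in range(config.n_nonforager)
    ]
    group = np.array([0] * config.n_forager + [1] * config.n_nonforager, dtype=np.int64)
    theta = np.empty((S, 9))
    theta[:, 0] = rng.normal(config.mu_gamma, config.sd_gamma, S)
    theta[:, 1] = rng.normal(config.mu_beta0, config.sd_beta0, S)
    for col, mus, sds in (
        (2, config.mu_beta1, config.sd_beta1),
        (3, config.mu_beta2, config.sd_beta2),
        (4, config.mu_beta3, config.sd_beta3),
    ):
        theta[:, col] = rng.normal(
            np.asarray(mus)[group], np.asarray(sds)[group]
        )
    theta[:, 5] = rng.normal(config.mu_beta4, config.sd_beta4, S)
    theta[:, 6] = rng.normal(config.mu_beta5, config.sd_beta5, S)
    theta[:, 7] = rng.normal(config.mu_beta6, config.sd_beta6, S)
    theta[:, 8] = _logit(rng.beta(*config.psi0_beta, size=S))
    alpha = rng.normal(0.0, config.sigma_alpha, size=len(config.years))
    hyper_mu = {
        "gamma": config.mu_gamma, "beta0": config.mu_beta0,
        "beta1_forager": config.mu_beta1[0], "beta1_nonforager": config.mu_beta1[1],
        "beta2_forager": config.mu_beta2[0], "beta2_nonforager": config.mu_beta2[1],
        "beta3_forager": config.mu_beta3[0], "beta3_nonforager": config.mu_beta3[1],
        "beta4": config.mu_beta4, "beta5": config.mu_beta5, "beta6": config.mu_beta6,
    }
    hyper_sd = {
        "gamma": config.sd_gamma, "beta0": config.sd_beta0,
        "beta1_forager": config.sd_beta1[0], "beta1_nonforager": config.sd_beta1[1],
        "beta2_forager": config.sd_beta2[0], "beta2_nonforager": config.sd_beta2[1],
        "beta3_forager": config.sd_beta3[0], "beta3_nonforager": config.sd_beta3[1],
        "beta4": config.sd_beta4, "beta5": config.sd_beta5, "beta6": config.sd_beta6,
    }
    return TrueParams(species, group, theta, alpha, hyper_mu, hyper_sd)


def simulate_dynamics(
    params: TrueParams,
    cov: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent occupancy z (S, J, T) from the transition model.

    ``cov`` is (J, T-1, 3) centred lagged covariates (osr, neonic, fii).
    """
    S = len(params.species)
    J, Tm1, _ = cov.shape
    T = Tm1 + 1
    z = np.empty((S, J, T), dtype=np.int8)
    psi0 = inv_logit(params.theta[:, 8])
    gamma = inv_logit(params.theta[:, 0])
    z[:, :, 0] = rng.random((S, J)) < psi0[:, None]
    for t in range(1, T):
        logits = (
            params.theta[:, 1, None]
            + params.theta[:, 2, None] * cov[None, :, t - 1, 0]
            + params.theta[:, 3, None] * cov[None, :, t - 1, 1]
            + params.theta[:, 4, None] * cov[None, :, t - 1, 2]
        )
        phi = inv_logit(logits)  # (S, J)
        prob = np.where(z[:, :, t - 1] == 1, phi, gamma[:, None])
        z[:, :, t] = rng.random((S, J)) < prob
    return z


_CLASS_BANDS = {0: (1, 1), 1: (2, 3), 2: (4, 7)}


def simulate_visits(
    z: np.ndarray,
    params: TrueParams,
    config: SimConfig,
    rng: np.random.Generator,
    sites: list[str],
    cell_lookup: pd.DataFrame,
):
    """Draw volunteer visits and detections; returns (records, visits_df).

    Every visit yields at least one record (a survey exists only because
    something was recorded); filler species pad lists toward the latent
    effort class's target length.  ``visits_df`` carries both the latent
    class and the realised list so both covariate conventions are
    available downstream.
    """
    S, J, T = z.shape
    years = config.years
    site_index = {s: j for j, s in enumerate(sites)}
    cells = cell_lookup["cell1km_id"].tolist()
    parent = cell_lookup["cell5km_id"].tolist()
    scale = config.visit_rate_mean / config.visit_rate_shape
    cell_rates = rng.gamma(config.visit_rate_shape, scale, size=len(cells))
    fillers = np.array([f"bkg_sp{k:03d}" for k in range(config.n_filler_species)])
    b4, b5, b6 = params.theta[:, 5], params.theta[:, 6], params.theta[:, 7]
    class_probs = np.asarray(config.list_class_probs, dtype=float)
    class_probs = class_probs / class_probs.sum()

    rec_species: list[str] = []
    rec_dates: list[str] = []
    rec_cells: list[str] = []
    visit_rows = []
    # per (class, year) modelled detection probabilities
    p_by_class = np.empty((3, T, S))
    for c in range(3):
        off = np.zeros(S) if c == 0 else (b5 if c == 1 else b6)
        p_by_class[c] = inv_logit(b4[None, :] + off[None, :] + params.alpha[:, None])

    for ci, (cell, site) in enumerate(zip(cells, parent)):
        j = site_index[site]
        for t, year in enumerate(years):
            if rng.random() < config.p_cellyear_inactive:
                continue
            n_visits = rng.poisson(cell_rates[ci])
            if n_visits == 0:
                continue
            days = rng.choice(365, size=min(n_visits, 365), replace=False)
            for day in days:
                date = (
                    pd.Timestamp(int(year), 1, 1) + pd.Timedelta(int(day), "D")
                ).strftime("%Y-%m-%d")
                klass = int(rng.choice(3, p=class_probs))
                occ = z[:, j, t] == 1
                detect = occ & (rng.random(S) < p_by_class[klass, t])
                detected = [params.species[i] for i in np.nonzero(detect)[0]]
                lo, hi = _CLASS_BANDS[klass]
                target = int(rng.integers(lo, hi + 1))
                n_fill = max(target - len(detected), 1 - len(detected), 0)
                fill = (
                    rng.choice(fillers, size=n_fill, replace=False).tolist()
                    if n_fill
                    else []
                )
                names = detected + fill
                for sp in names:
                    rec_species.append(sp)
                    rec_dates.append(date)
                    rec_cells.append(cell)
                visit_rows.append(
                    {
                        "cell1km_id": cell,
                        "cell5km_id": site,
                        "date": date,
                        "year": int(year),
                        "effort_class": klass,
                        "n_modelled_detections": len(detected),
                        "list_length": len(names),
                        "detected": detected,
                    }
                )
    records = pd.DataFrame(
        {"species": rec_species, "date": rec_dates, "cell1km_id": rec_cells}
    )
    records = records.sort_values(
        ["date", "cell1km_id", "species"], ignore_index=True
    )
    visits_df = pd.DataFrame(visit_rows)
    return records, visits_df


def _dataset_from_visits(
    visits_df: pd.DataFrame, params: TrueParams, sites: list[str], years: np.ndarray
) -> DetectionDataset:
    """Direct detection tensor using realised list categories."""
    S = len(params.species)
    sp_index = {s: i for i, s in enumerate(params.species)}
    j_of = {s: j for j, s in enumerate(sites)}
    t_of = {int(y): t for t, y in enumerate(years)}
    visit_counts = np.zeros((len(sites), len(years), 3), dtype=np.int64)
    det_counts = np.zeros((S, len(sites), len(years), 3), dtype=np.int64)
    for row in visits_df.itertuples(index=False):
        L = row.list_length
        cat = 0 if L == 1 else (1 if L <= 3 else 2)
        j, t = j_of[row.cell5km_id], t_of[row.year]
        visit_counts[j, t, cat] += 1
        for sp in row.detected:
            det_counts[sp_index[sp], j, t, cat] += 1
    return DetectionDataset(
        species=list(params.species),
        forager=params.forager,
        sites=list(sites),
        years=years,
        visit_counts=visit_counts,
        det_counts=det_counts,
    )


def simulate_study(config: SimConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study: tables, truth and dataset."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    sites, cell_lookup, cell_regions = simulate_landscape(config)
    osr_cover, neonic_treated, usage, properties = simulate_covariates(
        config, rng, sites, cell_regions
    )
    fii_panel = build_fii_panel(usage, properties, cell_regions)
    panel = build_covariate_panel(
        osr_cover, neonic_treated, fii_panel, cell_regions,
        years=(config.first_year, config.last_year - 1),
        osr_scale=OSR_MODEL_SCALE,
    )
    params = simulate_params(config, rng)
    arrays = panel.to_arrays(cells=np.asarray(sites))
    cov = np.stack([arrays["osr"], arrays["neonic"], arrays["fii"]], axis=2)
    z = simulate_dynamics(params, cov, config, rng)
    records, visits_df = simulate_visits(z, params, config, rng, sites, cell_lookup)
    dataset = _dataset_from_visits(visits_df, params, sites, config.years)
    traits = pd.DataFrame(
        {"species": params.species, "osr_forager": (params.group == 0).astype(int)}
    )
    tables = {
        "records": records,
        "osr_cover": osr_cover,
        "neonic_treated": neonic_treated,
        "pesticide_usage": usage,
        "pesticide_properties": properties,
        "cell_regions": cell_regions,
        "cell_lookup": cell_lookup,
        "species_traits": traits,
    }
    truth = SimulationTruth(params=params, z=z, panel=panel, config=config, seed=seed)
    return SyntheticStudy(tables=tables, truth=truth, dataset=dataset)
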