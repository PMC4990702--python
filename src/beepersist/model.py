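"""The multi-species dynamic occupancy-detection model.

``OccupancyModel`` bundles a :class:`~beepersist.surveys.DetectionDataset`
with a centred :class:`~beepersist.covariates.CovariatePanel` and fits the
hierarchical Bayesian model by MCMC:

* occupancy: z[i,j,1] ~ Bernoulli(psi0_i); thereafter an occupied cell
  persists with phi[i,j,t] = logit^-1(beta0_i + beta1_i*OSR + beta2_i*neonic
  + beta3_i*FII), covariates centred and lagged one year, and an empty
  cell is colonised with probability gamma_i;
* detection: visit k in year t detects an occupying species i with
  p = logit^-1(beta4_i + beta5_i*short + beta6_i*long + alpha_t);
* hierarchy: species effects are random; the persistence covariate
  coefficients (beta1..beta3) are drawn from separate distributions for
  oilseed-rape foragers and non-foragers, all other species effects from
  a single common distribution.

Priors are weakly informative: Normal(0, 10) on hyper-means, half-Normal
(2.5) on hyper-SDs (half-Cauchy available), Uniform(0,1) on initial
occupancy.  ``fit`` returns an :class:`~beepersist.posterior.OccupancyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .covariates import CovariatePanel
from .surveys import DetectionDataset
from . import sampler as _sampler
from .sampler import HYPER_NAMES, hyper_index_matrix

__all__ = ["FitConfig", "OccupancyModel", "fit_mcmc", "rhat"]

#: map from covariate name to the persistence coefficient it multiplies
COVARIATE_COEF = {"osr": "beta1", "neonic": "beta2", "fii": "beta3"}


@dataclass
class FitConfig:
    """MCMC protocol and prior settings.

    Defaults follow the long-run protocol (3 chains of 10,000 iterations,
    burn-in 5,000, thinning 3); scaled-down runs pass shorter values.
    """

    chains: int = 3
    iterations: int = 10_000
    burnin: int = 5_000
    thin: int = 3
    seed: int = 0
    mu_prior_sd: float = 10.0
    sd_prior_scale: float = 2.5
    sd_prior: str = "half-normal"  # or "half-cauchy"
    sampler: str = "marginal"  # or "augmented"
    rhat_threshold: float = 1.1
    sample_hypers: bool = True
    adapt: bool = True
    init_sigma_alpha: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def sd_prior_kind(self) -> int:
        kinds = {"half-normal": 0, "half-cauchy": 1}
        if self.sd_prior not in kinds:
            raise ValueError(f"unknown hyper-SD prior {self.sd_prior!r}")
        return kinds[self.sd_prior]


def rhat(chains: np.ndarray, split: bool = False) -> float:
    """Gelman–Rubin potential scale reduction factor for one scalar.

    ``chains`` is (n_chains, n_draws).  The classic between/within
    variance-ratio form is used; pass ``split=True`` to halve each chain
    first (sensitive to within-chain trend).  Finite-sample noise can push
    the raw ratio marginally below one, so the result is floored at 1.0;
    identical chains therefore give exactly 1.0.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains with >= 2 draws each")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = float(np.mean(x.var(axis=1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return max(1.0, float(np.sqrt(var_plus / w)))


class OccupancyModel:
    """Dynamic multi-species occupancy model ready for MCMC fitting.

    Parameters
    ----------
    dataset
        Assembled detection data (species × site × year × list category).
    covariates
        Centred covariate panel; must cover every dataset site for the
        years ``years[0] .. years[-2]`` (persistence into year t uses the
        covariates of year t-1).
    """

    def __init__(self, dataset: DetectionDataset, covariates: CovariatePanel):
        self.dataset = dataset
        self.covariates = covariates
        lag_years = dataset.years[:-1]
        arrays = covariates.to_arrays(cells=np.asarray(dataset.sites), years=lag_years)
        # (J, T-1, 3) in the order osr, neonic, fii
        self.cov = np.stack([arrays["osr"], arrays["neonic"], arrays["fii"]], axis=2)
        self.det = dataset.det_counts.astype(np.float64)
        self.nvis = dataset.visit_counts.astype(np.float64)
        self.anydet = dataset.any_detection()
        self.group = np.where(dataset.forager, 0, 1).astype(np.int64)
        self.hidx = hyper_index_matrix(self.group)

    @classmethod
    def from_tables(
        cls,
        detections_long: pd.DataFrame,
        covariate_table: pd.DataFrame,
        covariate_means: dict[str, float],
        species_traits: pd.DataFrame,
    ) -> "OccupancyModel":
        """Build from long-form serialisations (see ``DetectionDataset.to_long``)."""
        from .surveys import CATEGORIES

        species = sorted(detections_long["species"].unique())
        traits = species_traits.set_index("species")["osr_forager"]
        sites = sorted(detections_long["cell5km_id"].unique())
        years = np.arange(
            detections_long["year"].min(), detections_long["year"].max() + 1
        )
        si = {s: i for i, s in enumerate(species)}
        ji = {s: j for j, s in enumerate(sites)}
        ti = {int(y): t for t, y in enumerate(years)}
        ci = {c: k for k, c in enumerate(CATEGORIES)}
        det = np.zeros((len(species), len(sites), len(years), 3), dtype=np.int64)
        vis = np.zeros((len(sites), len(years), 3), dtype=np.int64)
        d = detections_long
        det[
            d["species"].map(si), d["cell5km_id"].map(ji),
            d["year"].map(ti), d["category"].map(ci),
        ] = d["n_detections"]
        first = d.drop_duplicates(["cell5km_id", "year", "category"])
        vis[
            first["cell5km_id"].map(ji), first["year"].map(ti), first["category"].map(ci)
        ] = first["n_visits"]
        ds = DetectionDataset(
            species=species,
            forager=traits.loc[species].to_numpy(dtype=bool),
            sites=sites,
            years=years,
            visit_counts=vis,
            det_counts=det,
        )
        panel = CovariatePanel(table=covariate_table, means=covariate_means)
        return cls(ds, panel)

    # ------------------------------------------------------------------
    def _initial_values(self, rng: np.random.Generator):
        S = self.dataset.n_species
        T = self.dataset.n_years
        theta = np.empty((S, 9))
        # crude data-informed starting points, jittered per chain
        surveyed = self.dataset.surveyed()
        naive = np.array(
            [
                self.anydet[i][surveyed].mean() if surveyed.any() else 0.3
                for i in range(S)
            ]
        )
        naive = np.clip(naive, 0.05, 0.9)
        base = np.array([-2.0, 1.0, 0.0, 0.0, 0.0, -3.0, 1.0, 2.0, 0.0])
        theta[:] = base
        theta[:, 8] = np.log(naive) - np.log1p(-naive)
        theta += rng.normal(0.0, 0.25, size=theta.shape)
        alpha = rng.normal(0.0, 0.1, size=T)
        hyper_mu = np.empty(len(HYPER_NAMES))
        hyper_sd = np.full(len(HYPER_NAMES), 0.5)
        for h, (c, g) in enumerate(zip(_sampler._HYPER_COL, _sampler._HYPER_GRP)):
            mask = np.ones(S, dtype=bool) if g < 0 else (self.group == g)
            hyper_mu[h] = theta[mask, c].mean()
        return theta, alpha, hyper_mu, hyper_sd

    def fit(self, config: FitConfig | None = None, **overrides):
        """Run the MCMC and return an OccupancyResults.

        Keyword overrides replace fields of ``config`` (e.g.
        ``model.fit(iterations=2000, burnin=1000, thin=2, seed=7)``).
        """
        from .posterior import OccupancyResults

        config = config or FitConfig()
        if overrides:
            config = replace(config, **overrides)
        ss = np.random.SeedSequence(config.seed)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(config.chains)]

        outs = []
        for c, cseed in enumerate(chain_seeds):
            rng = np.random.default_rng(cseed)
            theta, alpha, hyper_mu, hyper_sd = self._initial_values(rng)
            if config.sampler == "marginal":
                out = _sampler.run_chain_marginal(
                    self.det, self.nvis, self.cov, self.anydet, self.hidx,
                    _sampler._HYPER_COL, _sampler._HYPER_GRP, self.group,
                    theta, alpha, hyper_mu, hyper_sd, config.init_sigma_alpha,
                    config.iterations, config.burnin, config.thin, cseed,
                    config.mu_prior_sd, config.sd_prior_scale,
                    config.sd_prior_kind, config.sample_hypers, config.adapt,
                )
            elif config.sampler == "augmented":
                out = _sampler.run_chain_augmented(
                    self.det, self.nvis, self.cov, self.anydet, self.hidx,
                    self.group, theta, alpha, hyper_mu, hyper_sd,
                    config.init_sigma_alpha,
                    config.iterations, config.burnin, config.thin, cseed,
                    mu_prior_sd=config.mu_prior_sd,
                    sd_prior_scale=config.sd_prior_scale,
                    sd_prior_kind=config.sd_prior_kind,
                    sample_hypers=config.sample_hypers,
                )
            else:
                raise ValueError(f"unknown sampler {config.sampler!r}")
            outs.append(out)

        draws = {
            "theta": np.stack([o[0] for o in outs]),       # (C, D, S, 9)
            "alpha": np.stack([o[1] for o in outs]),       # (C, D, T)
            "hyper_mu": np.stack([o[2] for o in outs]),    # (C, D, 11)
            "hyper_sd": np.stack([o[3] for o in outs]),    # (C, D, 11)
            "sigma_alpha": np.stack([o[4] for o in outs]),  # (C, D)
        }
        return OccupancyResults(
            model=self, draws=draws, config=config, chain_seeds=chain_seeds
        )


def fit_mcmc(
    dataset: DetectionDataset,
    covariates: CovariatePanel,
    config: FitConfig | None = None,
    **overrides,
):
    """Functional wrapper: build an OccupancyModel and fit it."""
    return OccupancyModel(dataset, covariates).fit(config, **overrides)
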