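"""Results-stage computations on the fitted posterior.

``OccupancyResults`` carries the posterior draws together with the model
they came from and exposes:

* ``summary()`` — posterior mean/SD/95% CI/R-hat for the monitored
  hyper-parameters;
* ``group_effect`` / ``group_difference`` — the forager vs non-forager
  persistence-effect summaries, with posterior sign fractions computed
  pairwise within draws;
* ``project_occupancy`` — expected occupied-cell trajectories per species
  under the factual covariates or an idealised no-neonicotinoid scenario
  (exposure zeroed on the raw scale from the first treatment year, then
  re-centred with the original fitting means);
* ``occupancy_loss`` — percent loss of extant (occupied) cells in the
  final modelled year attributable to the exposure, per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import COVARIATE_COEF, FitConfig, rhat
from .sampler import HYPER_NAMES, THETA_COLS
from .likelihood import inv_logit

__all__ = ["EffectSummary", "OccupancyResults"]

GROUPS = ("forager", "nonforager")


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one group-level persistence effect."""

    group: str
    covariate: str
    posterior_mean: float
    ci95_low: float
    ci95_high: float
    fraction_below_zero: float

    @property
    def fraction_above_zero(self) -> float:
        return 1.0 - self.fraction_below_zero


def _summarise(draws: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


class OccupancyResults:
    """Posterior draws and derived quantities of a fitted occupancy model."""

    def __init__(self, model, draws: dict, config: FitConfig, chain_seeds: list[int]):
        self.model = model
        self.draws = draws
        self.config = config
        self.chain_seeds = chain_seeds
        self._rhat_table: pd.DataFrame | None = None

    @classmethod
    def from_draws(cls, model, draws: dict, config: FitConfig | None = None):
        """Rebuild a results object from stored draw arrays (e.g. a
        ``draws.npz`` written by the CLI) and the model they came from."""
        keys = {"theta", "alpha", "hyper_mu", "hyper_sd", "sigma_alpha"}
        missing = keys - set(draws)
        if missing:
            raise KeyError(f"draws missing arrays: {sorted(missing)}")
        return cls(
            model=model,
            draws={k: np.asarray(draws[k]) for k in keys},
            config=config or FitConfig(),
            chain_seeds=[],
        )

    # ------------------------------------------------------------ access
    @property
    def n_chains(self) -> int:
        return self.draws["theta"].shape[0]

    @property
    def n_draws(self) -> int:
        """Kept draws per chain."""
        return self.draws["theta"].shape[1]

    def hyper_draws(self, name: str, kind: str = "mu") -> np.ndarray:
        """(chains, draws) array for one hyper-parameter by short name."""
        key = {"mu": "hyper_mu", "sd": "hyper_sd"}[kind]
        return self.draws[key][:, :, HYPER_NAMES.index(name)]

    def species_draws(self, param: str, species: str) -> np.ndarray:
        """(chains, draws) for one species-level parameter.

        ``param`` is one of beta0..beta6 (logit scale) or gamma/psi0
        (probability scale).
        """
        i = self.model.dataset.species.index(species)
        if param in ("gamma", "psi0"):
            col = {"gamma": 0, "psi0": 8}[param]
            return inv_logit(self.draws["theta"][:, :, i, col])
        col = THETA_COLS.index(param)
        return self.draws["theta"][:, :, i, col]

    # --------------------------------------------------------- diagnostics
    def rhat_table(self, n_species_monitored: int = 5) -> pd.DataFrame:
        """R-hat for all hyper-parameters plus a few species-level ones."""
        if self._rhat_table is not None:
            return self._rhat_table
        rows = []
        for h, name in enumerate(HYPER_NAMES):
            rows.append(("mu_" + name, rhat(self.draws["hyper_mu"][:, :, h])))
            rows.append(("sd_" + name, rhat(self.draws["hyper_sd"][:, :, h])))
        rows.append(("sigma_alpha", rhat(self.draws["sigma_alpha"])))
        rng = np.random.default_rng(self.config.seed)
        S = self.model.dataset.n_species
        picks = rng.choice(S * 9, size=min(n_species_monitored, S * 9), replace=False)
        for flat in np.sort(picks):
            i, c = divmod(int(flat), 9)
            name = f"{THETA_COLS[c]}[{self.model.dataset.species[i]}]"
            rows.append((name, rhat(self.draws["theta"][:, :, i, c])))
        self._rhat_table = pd.DataFrame(rows, columns=["parameter", "rhat"])
        return self._rhat_table

    @property
    def converged(self) -> bool:
        return bool(
            (self.rhat_table()["rhat"] <= self.config.rhat_threshold).all()
        )

    def summary(self) -> pd.DataFrame:
        """Posterior summary table for the hyper-parameters."""
        rows = []
        rh = dict(zip(self.rhat_table()["parameter"], self.rhat_table()["rhat"]))
        for kind, key in (("mu", "hyper_mu"), ("sd", "hyper_sd")):
            for h, name in enumerate(HYPER_NAMES):
                d = self.draws[key][:, :, h].ravel()
                mean, lo, hi = _summarise(d)
                rows.append(
                    {
                        "parameter": f"{kind}_{name}",
                        "mean": mean,
                        "sd": float(d.std(ddof=1)),
                        "ci95_low": lo,
                        "ci95_high": hi,
                        "rhat": rh.get(f"{kind}_{name}", np.nan),
                    }
                )
        d = self.draws["sigma_alpha"].ravel()
        mean, lo, hi = _summarise(d)
        rows.append(
            {
                "parameter": "sigma_alpha",
                "mean": mean,
                "sd": float(d.std(ddof=1)),
                "ci95_low": lo,
                "ci95_high": hi,
                "rhat": rh.get("sigma_alpha", np.nan),
            }
        )
        return pd.DataFrame(rows)

    def to_arviz(self):
        """Hyper-parameter draws as an arviz.InferenceData."""
        import arviz as az

        data = {
            f"mu_{n}": self.draws["hyper_mu"][:, :, h]
            for h, n in enumerate(HYPER_NAMES)
        }
        data.update(
            {
                f"sd_{n}": self.draws["hyper_sd"][:, :, h]
                for h, n in enumerate(HYPER_NAMES)
            }
        )
        data["sigma_alpha"] = self.draws["sigma_alpha"]
        return az.from_dict(posterior=data)

    # ------------------------------------------------------------- effects
    def _group_hyper_name(self, covariate: str, group: str) -> str:
        if covariate not in COVARIATE_COEF:
            raise KeyError(f"unknown covariate {covariate!r}; expected one of "
                           f"{sorted(COVARIATE_COEF)}")
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
        return f"{COVARIATE_COEF[covariate]}_{group}"

    def group_effect(self, covariate: str, group: str) -> EffectSummary:
        """Posterior summary of one group's persistence hyper-mean."""
        d = self.hyper_draws(self._group_hyper_name(covariate, group)).ravel()
        mean, lo, hi = _summarise(d)
        return EffectSummary(
            group=group,
            covariate=covariate,
            posterior_mean=mean,
            ci95_low=lo,
            ci95_high=hi,
            fraction_below_zero=float((d < 0).mean()),
        )

    def group_difference(self, covariate: str) -> dict:
        """Posterior of the non-forager minus forager hyper-mean difference.

        Computed pairwise within draws (same chain and iteration).  The
        sign convention (non-forager minus forager) makes the difference
        positive when foragers are the more negatively affected group.
        """
        f = self.hyper_draws(self._group_hyper_name(covariate, "forager"))
        nf = self.hyper_draws(self._group_hyper_name(covariate, "nonforager"))
        if f.shape != nf.shape:
            raise ValueError("group draws are not paired")
        diff = (nf - f).ravel()
        mean, lo, hi = _summarise(diff)
        return {
            "covariate": covariate,
            "draws": diff,
            "mean": mean,
            "ci95_low": lo,
            "ci95_high": hi,
            "fraction_above_zero": float((diff > 0).mean()),
        }

    def effects_table(self) -> pd.DataFrame:
        """All six group × covariate effect summaries as a table."""
        rows = []
        for cov in COVARIATE_COEF:
            for grp in GROUPS:
                e = self.group_effect(cov, grp)
                rows.append(
                    {
                        "group": grp,
                        "covariate": cov,
                        "mean": e.posterior_mean,
                        "ci95_low": e.ci95_low,
                        "ci95_high": e.ci95_high,
                        "fraction_below_zero": e.fraction_below_zero,
                    }
                )
        return pd.DataFrame(rows)

    # --------------------------------------------------------- projection
    def _scenario_cov(self, scenario: str, first_treatment_year: int) -> np.ndarray:
        """(J, T-1, 3) centred lagged covariates under a scenario."""
        cov = self.model.cov.copy()
        if scenario == "factual":
            return cov
        if scenario != "no_neonic":
            raise ValueError(f"unknown scenario {scenario!r}")
        years = self.model.dataset.years[:-1]
        if first_treatment_year > years[-1] + 1:
            raise ValueError(
                f"first treatment year {first_treatment_year} outside the "
                f"modelled range {years[0]}–{years[-1]}"
            )
        mean = self.model.covariates.means["neonic"]
        # zero the exposure on the raw scale, then re-centre with the
        # original fitting mean so the coefficients keep their meaning
        mask = years >= first_treatment_year
        cov[:, mask, 1] = 0.0 - mean
        return cov

    def project_occupancy(
        self,
        scenario: str = "factual",
        first_treatment_year: int = 2002,
        max_draws: int = 500,
    ) -> pd.DataFrame:
        """Expected occupied-cell proportion per species-year with 95% CI.

        For each posterior draw the expected occupancy is propagated from
        the draw's initial occupancy through the dynamics (fitted values,
        not conditioned year-by-year on the detections):
        psi[t] = psi[t-1]*phi[t] + (1-psi[t-1])*gamma, per site; the
        occupied-cell proportion is the site mean.  ``max_draws`` caps the
        number of posterior draws propagated (deterministically strided).
        """
        psi = self._project_draws(scenario, first_treatment_year, max_draws)
        # psi: (n_draws, S, T) site-mean occupancy
        years = self.model.dataset.years
        species = self.model.dataset.species
        mean = psi.mean(axis=0)
        lo, hi = np.percentile(psi, [2.5, 97.5], axis=0)
        rows = []
        for i, sp in enumerate(species):
            for t, y in enumerate(years):
                rows.append(
                    {
                        "species": sp,
                        "scenario": scenario,
                        "year": int(y),
                        "mean": mean[i, t],
                        "ci95_low": lo[i, t],
                        "ci95_high": hi[i, t],
                    }
                )
        return pd.DataFrame(rows)

    def _flat_theta(self, max_draws: int) -> np.ndarray:
        th = self.draws["theta"]
        C, D, S, P = th.shape
        flat = th.reshape(C * D, S, P)
        if C * D > max_draws:
            idx = np.linspace(0, C * D - 1, max_draws).astype(int)
            flat = flat[idx]
        return flat

    def _project_draws(
        self, scenario: str, first_treatment_year: int, max_draws: int
    ) -> np.ndarray:
        cov = self._scenario_cov(scenario, first_treatment_year)  # (J, T-1, 3)
        theta = self._flat_theta(max_draws)  # (N, S, 9)
        N, S, _ = theta.shape
        J = self.model.dataset.n_sites
        T = self.model.dataset.n_years
        gamma = inv_logit(theta[:, :, 0])  # (N, S)
        psi0 = inv_logit(theta[:, :, 8])
        out = np.empty((N, S, T))
        psi = np.broadcast_to(psi0[:, :, None], (N, S, J)).copy()
        out[:, :, 0] = psi.mean(axis=2)
        for t in range(1, T):
            x = (
                theta[:, :, 1, None]
                + theta[:, :, 2, None] * cov[None, None, :, t - 1, 0]
                + theta[:, :, 3, None] * cov[None, None, :, t - 1, 1]
                + theta[:, :, 4, None] * cov[None, None, :, t - 1, 2]
            )
            phi = inv_logit(x)  # (N, S, J)
            psi = psi * phi + (1.0 - psi) * gamma[:, :, None]
            out[:, :, t] = psi.mean(axis=2)
        return out

    def occupancy_loss(
        self,
        first_treatment_year: int = 2002,
        thresholds: tuple[float, ...] = (10.0, 15.0, 20.0),
        method: str = "draws",
        max_draws: int = 500,
    ) -> pd.DataFrame:
        """Percent of extant cells lost to the exposure, per species.

        Loss = 100 * (counterfactual - factual) / counterfactual expected
        occupied-cell proportion in the final modelled year.  With
        ``method='draws'`` (default) the ratio is formed within each
        posterior draw and averaged; ``method='mean'`` forms it from the
        posterior-mean trajectories.  Adds one boolean column per entry of
        ``thresholds``.
        """
        fac = self._project_draws("factual", first_treatment_year, max_draws)
        cf = self._project_draws("no_neonic", first_treatment_year, max_draws)
        f_fin, c_fin = fac[:, :, -1], cf[:, :, -1]
        if method == "draws":
            with np.errstate(divide="ignore", invalid="ignore"):
                loss = np.where(c_fin > 0, 100.0 * (c_fin - f_fin) / c_fin, np.nan)
            pct = np.nanmean(loss, axis=0)
        elif method == "mean":
            fm, cm = f_fin.mean(axis=0), c_fin.mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = np.where(cm > 0, 100.0 * (cm - fm) / cm, np.nan)
        else:
            raise ValueError(f"unknown method {method!r}")
        df = pd.DataFrame(
            {
                "species": self.model.dataset.species,
                "forager": self.model.dataset.forager,
                "pct_loss": pct,
            }
        )
        for thr in thresholds:
            df[f"loss_gt_{thr:g}pct"] = df["pct_loss"] > thr
        return df.sort_values("pct_loss", ascending=False, ignore_index=True)

    # ------------------------------------------------------------- plots
    def plot_effect_posteriors(self, ax=None):
        """Overlaid forager/non-forager posterior densities per covariate."""
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax_, cov in zip(axes, COVARIATE_COEF):
            for grp, color in zip(GROUPS, ("tab:blue", "tab:red")):
                d = self.hyper_draws(self._group_hyper_name(cov, grp)).ravel()
                ax_.hist(d, bins=40, density=True, alpha=0.5, color=color, label=grp)
            ax_.axvline(0, color="k", lw=0.8)
            ax_.set_title(cov)
        axes[0].legend()
        fig.tight_layout()
        return fig

    def plot_trajectories(self, species: list[str] | None = None,
                          first_treatment_year: int = 2002):
        """Factual vs no-neonicotinoid occupancy ribbons per species."""
        import matplotlib.pyplot as plt

        fac = self.project_occupancy("factual", first_treatment_year)
        cf = self.project_occupancy("no_neonic", first_treatment_year)
        species = species or self.model.dataset.species[:6]
        n = len(species)
        ncol = min(3, n)
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
        for k, sp in enumerate(species):
            ax = axes[k // ncol][k % ncol]
            for df, color, label in ((fac, "tab:red", "factual"),
                                     (cf, "tab:blue", "no neonicotinoids")):
                sub = df[df["species"] == sp]
                ax.plot(sub["year"], sub["mean"], color=color, label=label)
                ax.fill_between(sub["year"], sub["ci95_low"], sub["ci95_high"],
                                color=color, alpha=0.2)
            ax.set_title(sp, fontsize=9)
        axes[0][0].legend(fontsize=8)
        fig.tight_layout()
        return fig
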