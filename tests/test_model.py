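"""Model fitting: R-hat, determinism, smoke fits, sampler agreement."""

import numpy as np
import pytest

from beepersist.model import FitConfig, OccupancyModel, fit_mcmc, rhat


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        one = rng.normal(size=500)
        chains = np.stack([one, one, one])
        assert rhat(chains) == pytest.approx(1.0, abs=1e-6)

    def test_never_below_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            chains = rng.normal(size=(3, 50))
            assert rhat(chains) >= 1.0

    def test_same_distribution_chains_approach_one(self):
        rng = np.random.default_rng(2)
        vals = [rhat(rng.normal(size=(3, n))) for n in (50, 500, 50_000)]
        assert vals[-1] < 1.005
        assert vals[-1] <= vals[0] + 0.05

    def test_disjoint_chains_far_above_one(self):
        rng = np.random.default_rng(3)
        chains = np.stack([rng.normal(0, 1, 200), rng.normal(50, 1, 200)])
        assert rhat(chains) > 10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))

    def test_split_variant_detects_trend(self):
        drift = np.linspace(0, 5, 400)
        chains = np.stack([drift, drift + 0.01])
        assert rhat(chains, split=True) > rhat(chains)


@pytest.fixture(scope="module")
def tiny_fit(small_study):
    m = OccupancyModel(small_study.dataset, small_study.truth.panel)
    res = m.fit(FitConfig(chains=2, iterations=120, burnin=60, thin=2, seed=11))
    return res


class TestFitMechanics:
    def test_draw_shapes_follow_protocol(self, tiny_fit):
        C = tiny_fit.n_chains
        D = tiny_fit.n_draws
        assert C == 2 and D == 30  # (120 - 60) / 2
        S = tiny_fit.model.dataset.n_species
        assert tiny_fit.draws["theta"].shape == (C, D, S, 9)
        assert np.all(np.isfinite(tiny_fit.draws["theta"]))
        assert np.all(tiny_fit.draws["hyper_sd"] > 0)

    def test_same_seed_reproduces_draws_exactly(self, small_study):
        m = OccupancyModel(small_study.dataset, small_study.truth.panel)
        cfg = FitConfig(chains=2, iterations=40, burnin=20, thin=2, seed=5)
        a = m.fit(cfg)
        b = m.fit(cfg)
        np.testing.assert_array_equal(a.draws["theta"], b.draws["theta"])
        np.testing.assert_array_equal(a.draws["hyper_mu"], b.draws["hyper_mu"])

    def test_different_seeds_differ(self, small_study):
        m = OccupancyModel(small_study.dataset, small_study.truth.panel)
        a = m.fit(FitConfig(chains=1, iterations=40, burnin=20, thin=2, seed=5))
        b = m.fit(FitConfig(chains=1, iterations=40, burnin=20, thin=2, seed=6))
        assert not np.array_equal(a.draws["theta"], b.draws["theta"])

    def test_single_species_single_site_smoke(self, small_study):
        """Degenerate dataset: one species, one site still runs."""
        from beepersist.surveys import DetectionDataset

        ds0 = small_study.dataset
        ds = DetectionDataset(
            species=ds0.species[:1],
            forager=ds0.forager[:1],
            sites=ds0.sites[:1],
            years=ds0.years,
            visit_counts=ds0.visit_counts[:1],
            det_counts=ds0.det_counts[:1, :1],
        )
        res = fit_mcmc(
            ds, small_study.truth.panel,
            chains=2, iterations=30, burnin=10, thin=1, seed=3,
        )
        assert np.all(np.isfinite(res.draws["theta"]))

    def test_summary_table_and_convergence_metadata(self, tiny_fit):
        s = tiny_fit.summary()
        assert {"parameter", "mean", "ci95_low", "ci95_high", "rhat"} <= set(s.columns)
        assert (s["ci95_low"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["ci95_high"] + 1e-12).all()
        assert isinstance(tiny_fit.converged, bool)

    def test_from_tables_round_trip(self, small_study):
        """A model rebuilt from the long-form serialisation carries the
        same detection tensors as the original."""
        ds = small_study.dataset
        panel = small_study.truth.panel
        traits = small_study.tables["species_traits"]
        m_direct = OccupancyModel(ds, panel)
        m_tables = OccupancyModel.from_tables(
            ds.to_long(), panel.table, panel.means, traits
        )
        np.testing.assert_array_equal(m_direct.det, m_tables.det)
        np.testing.assert_array_equal(m_direct.nvis, m_tables.nvis)
        np.testing.assert_array_equal(m_direct.cov, m_tables.cov)
        np.testing.assert_array_equal(m_direct.group, m_tables.group)

    def test_rhat_table_monitors_hypers_and_species(self, tiny_fit):
        tab = tiny_fit.rhat_table()
        names = set(tab["parameter"])
        assert "mu_beta2_forager" in names
        assert "sigma_alpha" in names
        assert (tab["rhat"] >= 1.0).all()


class TestCalibration:
    def test_credible_intervals_cover_generating_hypers(self, small_config):
        """Weak simulation-based calibration: across replicate synthetic
        datasets, 95% credible intervals for the hyper-means contain the
        generating values at roughly the nominal rate."""
        from beepersist.sampler import HYPER_NAMES
        from beepersist.synthetic import simulate_study

        hits = total = 0
        for seed in range(6):
            study = simulate_study(small_config, seed=100 + seed)
            m = OccupancyModel(study.dataset, study.truth.panel)
            res = m.fit(FitConfig(chains=2, iterations=400, burnin=200, thin=2,
                                  seed=seed))
            truth = study.truth.params.hyper_mu
            # persistence-effect hyper-means: the estimands of interest
            for name in (
                "beta1_forager", "beta1_nonforager",
                "beta2_forager", "beta2_nonforager",
                "beta3_forager", "beta3_nonforager",
            ):
                d = res.hyper_draws(name).ravel()
                lo, hi = np.percentile(d, [2.5, 97.5])
                hits += int(lo <= truth[name] <= hi)
                total += 1
        assert hits / total >= 0.75, f"coverage {hits}/{total}"


class TestSamplerAgreement:
    """The marginal and the explicit-latent-state samplers target the
    same posterior; on a small dataset their posterior means must agree
    to within combined Monte-Carlo error."""

    @pytest.fixture(scope="class")
    def fit_pair(self, small_study):
        m = OccupancyModel(small_study.dataset, small_study.truth.panel)
        common = dict(chains=2, sample_hypers=False, seed=17)
        res_m = m.fit(FitConfig(
            sampler="marginal", iterations=900, burnin=300, thin=2, **common
        ))
        res_a = m.fit(FitConfig(
            sampler="augmented", iterations=450, burnin=150, thin=2, **common
        ))
        return res_m, res_a

    @pytest.mark.parametrize("param", ["gamma", "psi0", "beta0", "beta4"])
    def test_marginal_vs_augmented_posterior_means(self, small_study, fit_pair, param):
        res_m, res_a = fit_pair
        sp = small_study.dataset.species[0]
        a = res_m.species_draws(param, sp).mean()
        b = res_a.species_draws(param, sp).mean()
        scale = max(res_m.species_draws(param, sp).std(), 0.05)
        assert abs(a - b) < 4 * scale
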