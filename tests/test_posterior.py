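"""Results stage: effect summaries, differences, counterfactuals, loss."""

import numpy as np
import pandas as pd
import pytest

from beepersist.model import FitConfig, OccupancyModel
from beepersist.posterior import EffectSummary


@pytest.fixture(scope="module")
def fitted(small_study):
    m = OccupancyModel(small_study.dataset, small_study.truth.panel)
    return m.fit(FitConfig(chains=2, iterations=200, burnin=100, thin=2, seed=21))


class TestEffectSummaries:
    def test_hand_countable_summary(self, fitted):
        # overwrite one hyper-mean column with known draws
        res = fitted
        idx = 4  # beta2_forager
        saved = res.draws["hyper_mu"][:, :, idx].copy()
        vals = np.tile([-2.0, -1.0, 0.5, 1.0], res.n_chains * res.n_draws // 4 + 1)
        res.draws["hyper_mu"][:, :, idx] = vals[: res.n_chains * res.n_draws].reshape(
            res.n_chains, res.n_draws
        )
        try:
            e = res.group_effect("neonic", "forager")
            assert e.posterior_mean == pytest.approx(np.mean([-2, -1, 0.5, 1.0]), abs=0.3)
            assert 0.3 < e.fraction_below_zero < 0.7
            assert e.ci95_low <= e.posterior_mean <= e.ci95_high
        finally:
            res.draws["hyper_mu"][:, :, idx] = saved

    def test_all_negative_draws_give_fraction_one(self, fitted):
        res = fitted
        idx = 4
        saved = res.draws["hyper_mu"][:, :, idx].copy()
        res.draws["hyper_mu"][:, :, idx] = -np.abs(saved) - 0.01
        try:
            assert res.group_effect("neonic", "forager").fraction_below_zero == 1.0
        finally:
            res.draws["hyper_mu"][:, :, idx] = saved

    def test_unknown_parameter_lookup_fails(self, fitted):
        with pytest.raises(KeyError):
            fitted.group_effect("rainfall", "forager")
        with pytest.raises(KeyError):
            fitted.group_effect("neonic", "queens")

    def test_effects_table_covers_all_combinations(self, fitted):
        tab = fitted.effects_table()
        assert len(tab) == 6
        assert (tab["ci95_low"] <= tab["ci95_high"]).all()


class TestGroupDifference:
    def test_pairwise_difference_and_sign_convention(self, fitted):
        res = fitted
        f, nf = 4, 5  # beta2 forager / nonforager slots
        saved_f = res.draws["hyper_mu"][:, :, f].copy()
        saved_nf = res.draws["hyper_mu"][:, :, nf].copy()
        res.draws["hyper_mu"][:, :, f] = -1.37
        res.draws["hyper_mu"][:, :, nf] = -0.46
        try:
            d = res.group_difference("neonic")
            # foragers more negative -> difference positive, zero variance
            assert d["mean"] == pytest.approx(0.91)
            assert d["ci95_low"] == pytest.approx(0.91)
            assert d["fraction_above_zero"] == 1.0
        finally:
            res.draws["hyper_mu"][:, :, f] = saved_f
            res.draws["hyper_mu"][:, :, nf] = saved_nf

    def test_difference_consistency_with_marginal_means(self, fitted):
        d = fitted.group_difference("osr")
        e_f = fitted.group_effect("osr", "forager").posterior_mean
        e_nf = fitted.group_effect("osr", "nonforager").posterior_mean
        assert d["mean"] == pytest.approx(e_nf - e_f, abs=1e-12)


class TestProjection:
    def test_counterfactual_identity_when_beta2_zero(self, fitted):
        res = fitted
        saved = res.draws["theta"][:, :, :, 3].copy()
        res.draws["theta"][:, :, :, 3] = 0.0
        try:
            fac = res.project_occupancy("factual", max_draws=50)
            cf = res.project_occupancy("no_neonic", max_draws=50)
            np.testing.assert_array_equal(
                fac["mean"].to_numpy(), cf["mean"].to_numpy()
            )
        finally:
            res.draws["theta"][:, :, :, 3] = saved

    def test_counterfactual_dominates_with_negative_beta2(self, fitted):
        """With all beta2 draws < 0 and nonnegative exposure the
        no-neonicotinoid trajectory is >= factual within every draw."""
        res = fitted
        saved = res.draws["theta"][:, :, :, 3].copy()
        res.draws["theta"][:, :, :, 3] = -np.abs(saved) - 0.1
        try:
            fac = res._project_draws("factual", 2002, 60)
            cf = res._project_draws("no_neonic", 2002, 60)
            assert np.all(cf >= fac - 1e-12)
        finally:
            res.draws["theta"][:, :, :, 3] = saved

    def test_pre_treatment_years_identical(self, fitted):
        fac = fitted.project_occupancy("factual", max_draws=40)
        cf = fitted.project_occupancy("no_neonic", max_draws=40)
        pre_f = fac[fac["year"] < 2002]["mean"].to_numpy()
        pre_c = cf[cf["year"] < 2002]["mean"].to_numpy()
        np.testing.assert_array_equal(pre_f, pre_c)

    def test_proportions_in_unit_interval(self, fitted):
        fac = fitted.project_occupancy("factual", max_draws=40)
        assert ((fac["mean"] >= 0) & (fac["mean"] <= 1)).all()
        assert (fac["ci95_low"] <= fac["ci95_high"]).all()

    def test_bad_scenario_or_year_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.project_occupancy("utopia")
        with pytest.raises(ValueError):
            fitted.project_occupancy("no_neonic", first_treatment_year=2050)


class TestOccupancyLoss:
    def test_loss_arithmetic(self, fitted):
        res = fitted
        fac = res._project_draws("factual", 2002, 40)
        cf = res._project_draws("no_neonic", 2002, 40)
        tab = res.occupancy_loss(max_draws=40, method="draws")
        # recompute one species by hand
        sp = res.model.dataset.species[0]
        i = res.model.dataset.species.index(sp)
        expected = np.mean(
            100 * (cf[:, i, -1] - fac[:, i, -1]) / cf[:, i, -1]
        )
        got = tab.set_index("species").loc[sp, "pct_loss"]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_identical_trajectories_mean_zero_loss(self, fitted):
        res = fitted
        saved = res.draws["theta"][:, :, :, 3].copy()
        res.draws["theta"][:, :, :, 3] = 0.0
        try:
            tab = res.occupancy_loss(max_draws=30)
            assert np.allclose(tab["pct_loss"], 0.0, atol=1e-10)
        finally:
            res.draws["theta"][:, :, :, 3] = saved

    def test_threshold_columns(self, fitted):
        tab = fitted.occupancy_loss(max_draws=30)
        for thr in (10, 15, 20):
            col = f"loss_gt_{thr}pct"
            assert col in tab.columns
            pd.testing.assert_series_equal(
                tab[col], tab["pct_loss"] > thr, check_names=False
            )

    def test_foragers_dominate_large_losses(self, fitted, small_study):
        """With the truth's strongly negative forager exposure effect,
        forager species head the loss ranking (evaluated at the known
        generating parameters to isolate the projection logic)."""
        res = fitted
        saved = res.draws["theta"].copy()
        truth = small_study.truth.params.theta
        res.draws["theta"] = np.broadcast_to(
            truth, res.draws["theta"].shape
        ).copy()
        try:
            tab = res.occupancy_loss(max_draws=4)
            n_f = int(small_study.dataset.forager.sum())
            top = tab.head(n_f)
            assert top["forager"].mean() > 0.5
            # mean loss among foragers exceeds that among non-foragers
            by_group = tab.groupby("forager")["pct_loss"].mean()
            assert by_group[True] > by_group[False]
        finally:
            res.draws["theta"] = saved
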