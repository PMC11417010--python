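"""Composite likelihood, optimization, ranking, and unit conversion."""

import numpy as np
import pandas as pd
import pytest

from demosfs.engine import expected_sfs_catalog
from demosfs.fit import (
    FitResult,
    PhysicalScale,
    composite_loglik,
    fit_model,
    profile_theta,
    rank_models,
    to_physical,
    _model_loglik,
)
from demosfs.sfs import SpectrumGrid


def single_entry_grids(obs_val, exp_val):
    v = np.zeros((3, 3))
    m = np.ones((3, 3), dtype=bool)
    m[1, 1] = False
    o = v.copy()
    o[1, 1] = obs_val
    e = v.copy()
    e[1, 1] = exp_val
    return SpectrumGrid(o, mask=m), SpectrumGrid(e, mask=m)


class TestCompositeLoglik:
    def test_single_entry_hand_value(self):
        o, e = single_entry_grids(1.0, 1.0)
        assert composite_loglik(o, e) == pytest.approx(-1.0)

    def test_all_zero_observed(self):
        o, e = single_entry_grids(0.0, 3.7)
        assert composite_loglik(o, e) == pytest.approx(-3.7)

    def test_scale_optimum_at_one(self):
        rng = np.random.default_rng(0)
        base = SpectrumGrid(rng.random((5, 5)) * 20)
        ll = [
            composite_loglik(base, SpectrumGrid(base.values * c, mask=base.mask))
            for c in (0.8, 0.9, 1.0, 1.1, 1.2)
        ]
        assert np.argmax(ll) == 2

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            composite_loglik(SpectrumGrid(np.ones((3, 3))), SpectrumGrid(np.ones((4, 3))))

    def test_fold_mismatch(self):
        a = SpectrumGrid(np.ones((3, 3)))
        with pytest.raises(ValueError, match="folded"):
            composite_loglik(a, a.fold())


class TestProfileTheta:
    def test_trivial_multiples(self):
        o, e = single_entry_grids(2.0, 1.0)
        assert profile_theta(o, e) == pytest.approx(2.0)
        o2, e2 = single_entry_grids(1.0, 1.0)
        assert profile_theta(o2, e2) == pytest.approx(1.0)

    def test_matches_numeric_maximization(self):
        rng = np.random.default_rng(1)
        obs = SpectrumGrid(rng.random((6, 4)) * 10)
        shape = SpectrumGrid(rng.random((6, 4)) * 2, mask=obs.mask)
        theta = profile_theta(obs, shape)
        grid = np.linspace(0.5 * theta, 1.5 * theta, 20001)
        lls = [
            composite_loglik(obs, SpectrumGrid(shape.values * t, mask=shape.mask))
            for t in grid
        ]
        assert abs(grid[int(np.argmax(lls))] - theta) <= 2 * (grid[1] - grid[0])

    def test_zero_mass_rejected(self):
        o, _ = single_entry_grids(1.0, 1.0)
        zero = SpectrumGrid(np.zeros((3, 3)), mask=o.mask)
        with pytest.raises(ValueError, match="zero unmasked mass"):
            profile_theta(o, zero)


class TestFitModel:
    def test_exact_recovery_sc2ns(self):
        true_p = [5.0, 0.1]
        obs = expected_sfs_catalog("sc2ns", true_p, 12, 12, theta=800.0).fold()
        fit = fit_model(obs, "sc2ns", restarts=4, seed=1)
        ll_true, _ = _model_loglik(obs, "sc2ns", true_p, 2)
        assert fit.log_likelihood >= ll_true - 1e-4  # optimum dominance
        assert fit.params[0] == pytest.approx(5.0, rel=0.02)
        assert fit.params[1] == pytest.approx(0.1, rel=0.02)
        assert fit.theta_hat == pytest.approx(800.0, rel=0.01)

    def test_seed_stability(self):
        obs = expected_sfs_catalog("sc2ns", [5.0, 0.1], 10, 10, theta=500.0).fold()
        f1 = fit_model(obs, "sc2ns", restarts=3, seed=10)
        f2 = fit_model(obs, "sc2ns", restarts=3, seed=99)
        assert abs(f1.log_likelihood - f2.log_likelihood) < 0.5

    def test_aic_identity(self):
        obs = expected_sfs_catalog("sc2ns", [5.0, 0.1], 10, 10, theta=500.0).fold()
        fit = fit_model(obs, "sc2ns", restarts=2, seed=0)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)
        assert fit.k == 3  # nu, T, theta

    def test_nested_dominance_s2m_over_s2msm(self):
        # the symmetric model is a constraint of the asymmetric one; with a
        # warm start at the symmetric optimum the asymmetric fit cannot be
        # meaningfully worse
        rng = np.random.default_rng(5)
        obs_vals = expected_sfs_catalog("s2msm", [2.0, 0.8, 0.15, 1.0], 8, 8, theta=300.0)
        noisy = SpectrumGrid(rng.poisson(obs_vals.values).astype(float), mask=obs_vals.mask)
        sym = fit_model(noisy, "s2msm", restarts=3, seed=2, guard=0)
        nu1, nu2, T, M = sym.params
        asym = fit_model(
            noisy,
            "s2m",
            restarts=2,
            seed=3,
            guard=0,
            start=np.array([nu1, nu2, T, M, M]),
        )
        assert asym.log_likelihood >= sym.log_likelihood - 1e-3

    def test_theta_free_model_sc1ns(self):
        obs = expected_sfs_catalog("sc1ns", [], 8, 8, theta=250.0).fold()
        fit = fit_model(obs, "sc1ns", restarts=1, seed=0)
        assert fit.theta_hat == pytest.approx(250.0, rel=1e-6)
        assert fit.k == 1


class TestRankModels:
    MEDIANS = {
        "sc2ns": 1948.72,
        "sc1ns": 1950.75,
        "sc3ns": 1952.63,
        "s2msm": 1968.08,
        "sc2el": 1998.72,
        "s2m": 2022.84,
        "sc2elsm": 2261.93,
    }

    def test_winner_statistics(self):
        r = rank_models(pd.DataFrame([self.MEDIANS]))
        assert r.index[0] == "sc2ns"
        assert r.loc["sc2ns", "delta_AIC"] == 0.0
        assert r.loc["sc2ns", "rel_likelihood"] == 1.0
        assert r["AIC_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_median_over_replicates(self):
        table = pd.DataFrame(
            {"a": [10.0, 12.0, 14.0], "b": [11.0, 11.5, 30.0]}
        )
        r = rank_models(table)
        assert r.loc["a", "median_AIC"] == 12.0
        assert r.loc["b", "median_AIC"] == 11.5
        assert r.index[0] == "b"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rank_models(pd.DataFrame({"a": [1.0], "b": [np.nan]}))


class TestToPhysical:
    def best_fit(self):
        mu, L = 3.92e-9, 4_971_503
        Ne = 10_263.0
        theta = 4 * Ne * mu * L
        params = np.array(
            [5.0, 4.7, 158_639 / Ne, 1_026_319 / Ne, 1_532 / (2 * Ne * 4.0), 2 * Ne * 4.87e-4]
        )
        return FitResult("gadma_best", params, theta, -920.78, 6), mu, L

    def test_migrants_per_generation(self):
        fit, mu, L = self.best_fit()
        ph = to_physical(fit, PhysicalScale(mu=mu, G=4.0, L=L))
        assert ph.migrants_per_generation["1to2"] == pytest.approx(77.0, abs=1.0)
        assert ph.migrant_fraction["1to2"] == pytest.approx(4.87e-4, rel=1e-6)

    def test_generation_time_rescaling(self):
        fit, mu, L = self.best_fit()
        y4 = to_physical(fit, PhysicalScale(mu=mu, G=4.0, L=L)).split_years
        y12 = to_physical(fit, PhysicalScale(mu=mu, G=12.0, L=L)).split_years
        assert y12 == pytest.approx(3 * y4)
        assert y12 == pytest.approx(4596, abs=5)

    def test_zero_theta_zero_sizes(self):
        fit, mu, L = self.best_fit()
        fit.theta_hat = 0.0
        ph = to_physical(fit, PhysicalScale(mu=mu, G=4.0, L=L))
        assert ph.Ne_anc == 0.0
        assert all(v == 0.0 for v in ph.Ne_current.values())

    def test_missing_length_rejected(self):
        fit, mu, L = self.best_fit()
        with pytest.raises(ValueError, match="L"):
            to_physical(fit, PhysicalScale(mu=mu, G=4.0, L=None))
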