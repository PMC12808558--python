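"""Likelihood, prior, MAP and MCMC machinery.

The forward-recursion marginal likelihood is checked against exhaustive
latent-state enumeration; the sampler is cross-checked against an
importance-sampling estimate of the same posterior on a tiny instance.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from occupam import model
from occupam.covariates import DesignSet
from occupam.detections import EncounterHistory
from occupam.model import (ParamVector, PosteriorDraws, PriorConfig,
                           convergence_report, enumerate_loglik, fit_map,
                           link_probs, log_prior, loglik_all, mb_chisq_ppc,
                           sample_posterior, site_loglik)
from tests.conftest import make_dataset


def random_instance(rng, T=None, J=None):
    """Random small site history + probabilities for oracle comparison."""
    T = T or int(rng.integers(1, 5))
    J = J or int(rng.integers(1, 6))
    p = rng.uniform(0.05, 0.95, (T, J))
    psi = rng.uniform(0.05, 0.95)
    gamma = rng.uniform(0.05, 0.95, max(T - 1, 1))
    eps = rng.uniform(0.05, 0.95, max(T - 1, 1))
    Y = (rng.random((T, J)) < 0.4).astype(float)
    Y[rng.random((T, J)) < 0.3] = np.nan
    return Y, psi, gamma, eps, p


class TestLinkProbs:
    def test_all_zero_parameters_give_half(self, small_dataset):
        design = small_dataset["design"]
        params = ParamVector.zeros_like_design(design)
        probs = link_probs(params, design)
        for key in ("psi", "gamma", "eps", "p"):
            np.testing.assert_allclose(probs[key], 0.5)

    def test_effort_effect_monotone(self, small_dataset):
        """beta_log_hours = 0.58 > 0: p rises with standardized effort."""
        design = small_dataset["design"]
        params = ParamVector.zeros_like_design(design)
        params.beta_p[0] = 0.58
        p = link_probs(params, design)["p"]
        x = design.X_p[:, :, :, 0]
        hi, lo = p[x > 1.0], p[x < -1.0]
        assert hi.size and lo.size and hi.min() > lo.max()

    def test_saturation_clipped(self, small_dataset):
        design = small_dataset["design"]
        params = ParamVector.zeros_like_design(design)
        params.alpha_psi[:] = 100.0
        psi = link_probs(params, design)["psi"]
        assert np.all(psi <= 1.0) and np.all(psi >= 1.0 - 1e-14)


class TestSiteLoglik:
    def test_single_year_single_week_closed_form(self):
        Y = np.array([[1.0]])
        ll = site_loglik(Y, np.ones((1, 1)), 0.3, [0.5], [0.5],
                        np.array([[0.7]]))
        assert ll == pytest.approx(np.log(0.3 * 0.7), abs=1e-10)

    def test_all_missing_is_zero(self):
        Y = np.full((3, 4), np.nan)
        ll = site_loglik(Y, np.zeros((3, 4)), 0.3, [0.2, 0.2], [0.4, 0.4],
                        np.full((3, 4), 0.5))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_detection_without_effort_rejected(self):
        Y = np.array([[1.0]])
        with pytest.raises(ValueError):
            site_loglik(Y, np.zeros((1, 1)), 0.3, [0.5], [0.5],
                        np.array([[0.7]]))

    def test_forward_equals_enumeration(self, rng):
        """Forward algorithm == brute-force 2^T path sum on 300 instances."""
        for _ in range(300):
            Y, psi, gamma, eps, p = random_instance(rng)
            fwd = site_loglik(Y, None, psi, gamma, eps, p)
            brute = enumerate_loglik(Y, psi, gamma, eps, p)
            assert fwd == pytest.approx(brute, abs=1e-12)

    def test_site_permutation_invariance(self, rng):
        n, T, J = 12, 3, 4
        Y = (rng.random((n, T, J)) < 0.3).astype(float)
        Y[rng.random((n, T, J)) < 0.2] = np.nan
        psi = rng.uniform(0.2, 0.8, n)
        gamma = rng.uniform(0.1, 0.5, (n, T - 1))
        eps = rng.uniform(0.1, 0.5, (n, T - 1))
        p = rng.uniform(0.2, 0.8, (n, T, J))
        base = loglik_all(Y, psi, gamma, eps, p).sum()
        perm = rng.permutation(n)
        permuted = loglik_all(Y[perm], psi[perm], gamma[perm], eps[perm],
                              p[perm]).sum()
        assert permuted == pytest.approx(base, rel=1e-12)

    def test_extra_missing_week_no_effect(self, rng):
        Y, psi, gamma, eps, p = random_instance(rng, T=3, J=4)
        base = site_loglik(Y, None, psi, gamma, eps, p)
        Y2 = np.concatenate([Y, np.full((3, 1), np.nan)], axis=1)
        p2 = np.concatenate([p, np.full((3, 1), 0.5)], axis=1)
        assert site_loglik(Y2, None, psi, gamma, eps, p2) == pytest.approx(
            base, abs=1e-12)

    def test_independence_limit(self, rng):
        """With gamma = psi' and eps = 1 - psi' the years decouple into
        independent single-season models sharing occupancy psi'."""
        T, J = 3, 4
        psi0 = 0.37
        Y, _, _, _, p = random_instance(rng, T=T, J=J)
        gamma = np.full(T - 1, psi0)
        eps = np.full(T - 1, 1 - psi0)
        joint = site_loglik(Y, None, psi0, gamma, eps, p)
        single = 0.0
        for t in range(T):
            obs = ~np.isnan(Y[t])
            l1 = np.prod(np.where(obs, p[t] ** np.nan_to_num(Y[t])
                                  * (1 - p[t]) ** (1 - np.nan_to_num(Y[t])), 1.0))
            l0 = 0.0 if np.nansum(Y[t]) > 0 else 1.0
            single += np.log(psi0 * l1 + (1 - psi0) * l0)
        assert joint == pytest.approx(single, abs=1e-10)


class TestPrior:
    def test_zero_coefficient_is_mode(self, small_dataset):
        design = small_dataset["design"]
        base = ParamVector.zeros_like_design(design, sigma_psi=1.0,
                                             sigma_gamma=1.0, sigma_eps=1.0,
                                             sigma_p=1.0)
        lp0 = log_prior(base)
        pert = ParamVector.zeros_like_design(design, sigma_psi=1.0,
                                             sigma_gamma=1.0, sigma_eps=1.0,
                                             sigma_p=1.0)
        pert.beta_psi[0] = 0.5
        assert log_prior(pert) < lp0

    def test_gaussian_coefficient_penalty(self, small_dataset):
        design = small_dataset["design"]
        a = ParamVector.zeros_like_design(design)
        b = ParamVector.zeros_like_design(design)
        b.beta_gamma[0] = 2.0
        delta = log_prior(a) - log_prior(b)
        assert delta == pytest.approx(2.0 ** 2 / (2 * 2.5 ** 2), abs=1e-10)

    def test_sigma_to_zero_finite_density(self, small_dataset):
        """Half-Cauchy stays finite at the origin (no spike at sigma=0)."""
        design = small_dataset["design"]
        p = ParamVector.zeros_like_design(design, sigma_psi=1e-8)
        lp = log_prior(p, jacobian=False)
        assert np.isfinite(lp)
        dens_small = stats.halfcauchy.logpdf(1e-8, scale=2.5)
        assert dens_small == pytest.approx(np.log(2 / (np.pi * 2.5)), abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ParamVector(beta_psi=[0.0], beta_gamma=[0.0], beta_eps=[0.0],
                        beta_p=[0.0], alpha_psi=[0.0], alpha_gamma=[0.0],
                        alpha_eps=[0.0], alpha_p=[0.0], sigma_psi=0.0)


class TestBatchPosterior:
    def test_batch_matches_scalar(self, small_dataset, rng):
        design = small_dataset["design"]
        hist = small_dataset["history"]
        template = ParamVector.zeros_like_design(design)
        prior = PriorConfig()
        V = rng.normal(0, 0.4, (25, len(template.to_vector())))
        scalar = np.array([model.log_posterior(v, template, design, hist.Y, prior)
                           for v in V])
        batch = model.log_posterior_batch(V, template, design, hist.Y, prior)
        np.testing.assert_allclose(batch, scalar, rtol=1e-10, atol=1e-8)

    def test_vector_round_trip(self, small_dataset, rng):
        design = small_dataset["design"]
        template = ParamVector.zeros_like_design(design)
        v = rng.normal(0, 1, len(template.to_vector()))
        back = ParamVector.from_vector(v, template).to_vector()
        np.testing.assert_allclose(back, v)


def tiny_intercept_problem(n=40, T=1, J=3, psi=0.7, p=0.5, seed=0):
    """Intercept-only model (no covariates, one forest): 12 parameters."""
    rng = np.random.default_rng(seed)
    z = rng.random(n) < psi
    Y = (rng.random((n, T, J)) < (z[:, None, None] * p)).astype(float)
    eff = np.ones((n, T, J))
    hist = EncounterHistory(Y=Y, effort=eff, site_ids=list(range(n)),
                            years=list(range(2021, 2021 + T)))
    design = DesignSet(
        X_psi=np.zeros((n, 0)), X_gamma=np.zeros((n, T - 1, 0)),
        X_eps=np.zeros((n, T - 1, 0)), X_p=np.zeros((n, T, J, 0)),
        forest_index=np.zeros(n, dtype=int), n_forests=1,
        psi_cols=[], trans_cols=[], p_cols=[],
        years=list(range(2021, 2021 + T)), site_ids=list(range(n)))
    return hist, design


class TestFitMap:
    def test_recovery_single_season(self):
        """n=500, psi=0.8, p=0.9: the mode recovers psi closely."""
        hist, design = tiny_intercept_problem(n=500, psi=0.8, p=0.9, seed=3)
        res = fit_map(hist, design, optimizer_config={"n_starts": 2})
        psi_hat = expit(res.params.alpha_psi[0])
        assert res.converged
        assert psi_hat == pytest.approx(0.8, abs=0.06)
        # and within 3 SEs on the logit scale where the SE is defined
        idx = res.names.index("alpha_psi[0]")
        if np.isfinite(res.se[idx]):
            assert abs(res.vector[idx] - logit(0.8)) < 3 * res.se[idx] + 1e-6

    def test_all_missing_not_identified(self):
        hist, design = tiny_intercept_problem(n=20, seed=1)
        hist.Y[:] = np.nan
        hist.effort[:] = 0.0
        with pytest.raises(ValueError):
            fit_map(hist, design)

    def test_map_beats_truth(self, small_dataset):
        """The optimized posterior is at least as high as at the truth."""
        hist, design = small_dataset["history"], small_dataset["design"]
        truth = small_dataset["params"]
        res = fit_map(hist, design, optimizer_config={"n_starts": 1,
                                                      "compute_se": False})
        template = ParamVector.zeros_like_design(design)
        lp_truth = model.log_posterior(truth.to_vector(), template, design,
                                       hist.Y, PriorConfig())
        assert res.log_posterior >= lp_truth - 1e-6


class TestSamplePosterior:
    def test_seed_determinism(self):
        import warnings as _w
        hist, design = tiny_intercept_problem(seed=2)
        kw = dict(chains=1, iter=120, warmup=60, seed=11, n_walkers=26)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            a = sample_posterior(hist, design, **kw)
            b = sample_posterior(hist, design, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_matches_random_walk_metropolis(self):
        """Ensemble-sampler means agree with an independent random-walk
        Metropolis sampler targeting the same 12-dim posterior."""
        hist, design = tiny_intercept_problem(n=60, psi=0.6, p=0.6, seed=5)
        prior = PriorConfig()
        template = ParamVector.zeros_like_design(design)
        res = fit_map(hist, design, prior, {"n_starts": 2,
                                            "compute_se": False})
        ndim = len(res.vector)
        ws = model.PosteriorWorkspace(template, design, hist.Y, prior)

        # oracle: 64 parallel RW-MH chains, component-free Gaussian steps
        rng = np.random.default_rng(7)
        K, steps, warm = 64, 2500, 800
        x = res.vector[None, :] + 0.05 * rng.standard_normal((K, ndim))
        lp = ws(x)
        scale = 0.25
        keep = []
        for s in range(steps):
            prop = x + scale * rng.standard_normal((K, ndim))
            lp_prop = ws(prop)
            acc = np.log(rng.random(K)) < (lp_prop - lp)
            x = np.where(acc[:, None], prop, x)
            lp = np.where(acc, lp_prop, lp)
            if s >= warm:
                keep.append(x.copy())
        oracle = np.concatenate(keep, axis=0)

        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            draws = sample_posterior(hist, design, prior, chains=1, iter=900,
                                     warmup=450, seed=9)
        mc_mean = draws.flat().mean(axis=0)
        or_mean = oracle.mean(axis=0)
        i_psi = draws.names.index("alpha_psi[0]")
        i_p = draws.names.index("alpha_p[0]")
        for i in (i_psi, i_p):
            assert mc_mean[i] == pytest.approx(or_mean[i], abs=0.15)

    def test_iter_must_exceed_warmup(self):
        hist, design = tiny_intercept_problem()
        with pytest.raises(ValueError):
            sample_posterior(hist, design, iter=100, warmup=100)


class TestEstimatorFacade:
    def test_map_fit_sets_fitted_attributes(self):
        hist, design = tiny_intercept_problem(n=80, psi=0.6, p=0.7, seed=6)
        est = model.DynamicOccupancyModel(method="map")
        est.fit(hist, design, n_starts=2, compute_se=False)
        assert hasattr(est, "params_") and hasattr(est, "loglik_")
        probs = est.predict_proba()
        assert set(probs) == {"psi", "gamma", "eps", "p"}
        assert est.score(hist) == pytest.approx(est.loglik_)

    def test_get_set_params_round_trip(self):
        est = model.DynamicOccupancyModel(method="map", chains=2)
        params = est.get_params()
        assert params["chains"] == 2
        est.set_params(chains=4)
        assert est.get_params()["chains"] == 4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)


class TestConvergenceReport:
    def test_constant_chains_flagged(self):
        arr = np.ones((2, 200, 1))
        d = PosteriorDraws(draws=arr, names=["a"], template=None)
        rep = convergence_report(d)
        assert not rep["pass"].iloc[0]

    def test_iid_normal_passes(self, rng):
        arr = rng.standard_normal((4, 1000, 2))
        d = PosteriorDraws(draws=arr, names=["a", "b"], template=None)
        rep = convergence_report(d)
        assert (rep["rhat"] < 1.01).all()
        assert rep["ess_bulk"].between(0.8 * 4000, 1.25 * 4000).all()
        assert rep["pass"].all()

    def test_shifted_chain_fails(self, rng):
        arr = rng.standard_normal((3, 500, 1))
        arr[0] += 5.0
        d = PosteriorDraws(draws=arr, names=["a"], template=None)
        rep = convergence_report(d)
        assert rep["rhat"].iloc[0] > 1.01
        assert not rep["pass"].iloc[0]

    def test_single_chain_error(self, rng):
        d = PosteriorDraws(draws=rng.standard_normal((1, 100, 1)),
                           names=["a"], template=None)
        with pytest.raises(ValueError):
            convergence_report(d)


class TestGoodnessOfFit:
    @staticmethod
    def _plugin_draws(hist, design, n=60, jitter=0.02, seed=0):
        res = fit_map(hist, design, optimizer_config={"n_starts": 1,
                                                      "compute_se": False})
        rng = np.random.default_rng(seed)
        flat = res.vector[None, :] + jitter * rng.standard_normal(
            (n, len(res.vector)))
        return PosteriorDraws(draws=flat[None], names=res.names,
                              template=ParamVector.zeros_like_design(design))

    def test_misspecified_data_small_p(self):
        """Gross site heterogeneity in p inflates chi-square: small p."""
        rng = np.random.default_rng(4)
        n, T, J = 120, 1, 6
        z = rng.random(n) < 0.6
        p_i = np.where(np.arange(n) < n // 2, 0.97, 0.03)
        Y = (rng.random((n, T, J)) < (z[:, None, None] * p_i[:, None, None])
             ).astype(float)
        hist = EncounterHistory(Y=Y, effort=np.ones((n, T, J)),
                                site_ids=list(range(n)), years=[2021])
        design = DesignSet(
            X_psi=np.zeros((n, 0)), X_gamma=np.zeros((n, 0, 0)),
            X_eps=np.zeros((n, 0, 0)), X_p=np.zeros((n, T, J, 0)),
            forest_index=np.zeros(n, dtype=int), n_forests=1,
            psi_cols=[], trans_cols=[], p_cols=[], years=[2021],
            site_ids=list(range(n)))
        draws = self._plugin_draws(hist, design, seed=1)
        res = mb_chisq_ppc(draws, hist, design, n_reps=60, seed=2)
        assert res.p_value < 0.05

    def test_low_reps_warns(self):
        hist, design = tiny_intercept_problem(seed=8)
        draws = self._plugin_draws(hist, design, n=20, seed=3)
        with pytest.warns(RuntimeWarning):
            mb_chisq_ppc(draws, hist, design, n_reps=10, seed=4)
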