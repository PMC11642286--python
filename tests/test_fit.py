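"""Discrepancy, posterior predictive assessment, DIC, fit indices."""

import math

import numpy as np
import pytest

import bcfa
from bcfa.exceptions import InsufficientDataError, MatrixValidityError
from bcfa.fit import _subsample, independence_draws
from bcfa.gibbs import PosteriorDraws


class TestMlDiscrepancy:
    def test_zero_at_perfect_fit(self):
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert bcfa.ml_discrepancy(s, s, 50) == pytest.approx(0.0, abs=1e-10)

    def test_hand_evaluated_2x2(self):
        # S = I, Sigma = diag(1, 2), n = 10:
        # F = ln 2 - 0 + (1 + 0.5) - 2 = ln 2 - 0.5
        s = np.eye(2)
        sigma = np.diag([1.0, 2.0])
        expected = 10 * (math.log(2.0) - 0.5)
        assert bcfa.ml_discrepancy(s, sigma, 10) == pytest.approx(expected)

    def test_linear_in_n(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4))
        s = a @ a.T + 4 * np.eye(4)
        sigma = s + 0.3 * np.eye(4)
        d1 = bcfa.ml_discrepancy(s, sigma, 100)
        d2 = bcfa.ml_discrepancy(s, sigma, 200)
        assert d2 == pytest.approx(2 * d1)

    def test_mean_term(self):
        s = np.eye(2)
        d = bcfa.ml_discrepancy(s, s, 10, mean_obs=np.array([0.5, 0.0]),
                                mean_model=np.zeros(2))
        assert d == pytest.approx(10 * 0.25)

    def test_singular_rejected(self):
        s = np.ones((2, 2))
        with pytest.raises(MatrixValidityError):
            bcfa.ml_discrepancy(s, np.eye(2) * 0.0, 10)

    def test_matches_independent_oracle_evaluator(self):
        # dual route: cho_factor-based discrepancy vs slogdet/solve evaluator
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 6))
        s = a @ a.T + 6 * np.eye(6)
        b = rng.normal(size=(6, 6))
        sigma = b @ b.T + 6 * np.eye(6)
        n = 123
        assert bcfa.ml_discrepancy(s, sigma, n) == pytest.approx(
            n * bcfa.ml_fit_function(s, sigma), abs=1e-6
        )


class TestPosteriorPredictive:
    def test_well_specified_ppp_central(self):
        """Median PPP over replicate well-specified datasets sits near 0.5
        and the discrepancy-difference interval straddles zero."""
        import warnings

        model = bcfa.cfa_generating_model()
        spec = bcfa.pih_cfa_spec()
        ppps, cover = [], 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(5):
                data = bcfa.generate_continuous(model, 300, seed=500 + s)
                std = bcfa.standardize(data)
                draws = bcfa.run_mcmc(spec, std, chains=2, min_iterations=800,
                                      max_iterations=800, seed=600 + s)
                res = bcfa.posterior_predictive_p(draws, std, seed=700 + s,
                                                  max_draws=200)
                ppps.append(res.ppp)
                lo, hi = res.discrepancy_diff_ci
                cover += lo < 0 < hi
        assert 0.3 <= float(np.median(ppps)) <= 0.7
        assert cover >= 4

    def test_ppp_is_proportion(self, cfa_fit, cfa_std):
        res = bcfa.posterior_predictive_p(cfa_fit, cfa_std, seed=78,
                                          max_draws=150)
        assert 0.0 <= res.ppp <= 1.0
        assert res.n_draws_used <= 150

    def test_insufficient_draws_rejected(self, cfa_fit, cfa_std):
        few = PosteriorDraws(
            lam=cfa_fit.lam[:1, :20], nu=cfa_fit.nu[:1, :20],
            phi=cfa_fit.phi[:1, :20], theta=cfa_fit.theta[:1, :20],
            spec=cfa_fit.spec, seed=0, n_iterations=40, psr={},
            converged=True, n_obs=cfa_fit.n_obs,
        )
        with pytest.raises(InsufficientDataError):
            bcfa.posterior_predictive_p(few, cfa_std, seed=79)

    def test_seed_reproducibility(self, cfa_fit, cfa_std):
        a = bcfa.posterior_predictive_p(cfa_fit, cfa_std, seed=80, max_draws=120)
        b = bcfa.posterior_predictive_p(cfa_fit, cfa_std, seed=80, max_draws=120)
        assert a.ppp == b.ppp
        assert a.discrepancy_diff_ci == b.discrepancy_diff_ci


class TestDic:
    def test_degenerate_single_draw(self, cfa_fit, cfa_std):
        one = cfa_fit.lam[:1, :1]
        draws = PosteriorDraws(
            lam=np.repeat(one, 120, axis=1),
            nu=np.repeat(cfa_fit.nu[:1, :1], 120, axis=1),
            phi=np.repeat(cfa_fit.phi[:1, :1], 120, axis=1),
            theta=np.repeat(cfa_fit.theta[:1, :1], 120, axis=1),
            spec=cfa_fit.spec, seed=0, n_iterations=240, psr={},
            converged=True, n_obs=cfa_fit.n_obs,
        )
        res = bcfa.dic(draws, cfa_std)
        assert res.pd == pytest.approx(0.0, abs=1e-6)
        assert res.dic == pytest.approx(res.deviance_at_mean, abs=1e-5)

    def test_true_spec_beats_one_factor(self, bsem_fit, onefactor_fit, bsem_std):
        dic_true = bcfa.dic(bsem_fit, bsem_std, max_draws=400)
        dic_bad = bcfa.dic(onefactor_fit, bsem_std, max_draws=400)
        assert dic_true.dic < dic_bad.dic

    def test_pd_order_of_parameter_count(self, cfa_fit, cfa_std):
        # effective parameters within a factor-2 window of the free count (42)
        res = bcfa.dic(cfa_fit, cfa_std, max_draws=400)
        n_par = bcfa.count_free_parameters(cfa_fit.spec)
        assert 0.5 * n_par <= res.pd <= 2.0 * n_par


class TestFitIndices:
    def test_well_specified_regime(self, cfa_fit, cfa_std):
        baseline = independence_draws(cfa_std, n_draws=cfa_fit.n_draws, seed=5)
        idx = bcfa.bayesian_fit_indices(cfa_fit, cfa_std, baseline,
                                        max_draws=400)
        assert idx.brmsea.median < 0.06
        assert idx.bcfi.median > 0.95
        assert idx.brmsea.label == "good" and idx.bcfi.label == "good"
        assert idx.brmsea.lower <= idx.brmsea.median <= idx.brmsea.upper

    def test_misfit_detected(self, onefactor_fit, bsem_std):
        baseline = independence_draws(bsem_std, n_draws=onefactor_fit.n_draws,
                                      seed=6)
        idx = bcfa.bayesian_fit_indices(onefactor_fit, bsem_std, baseline,
                                        max_draws=300)
        assert idx.bcfi.median < 0.9
        assert idx.brmsea.median > 0.06

    def test_bounds_respected(self, cfa_fit, cfa_std):
        baseline = independence_draws(cfa_std, n_draws=cfa_fit.n_draws, seed=7)
        idx = bcfa.bayesian_fit_indices(cfa_fit, cfa_std, baseline, max_draws=200)
        assert idx.brmsea.lower >= 0.0
        assert idx.bcfi.upper <= 1.0 and idx.btli.upper <= 1.0


def test_assess_fit_serializes(cfa_fit, cfa_std):
    summary = bcfa.assess_fit(cfa_fit, cfa_std, seed=90, max_draws=200)
    payload = summary.to_dict()
    assert payload["n_params"] == 42
    assert 0.0 <= payload["ppp"] <= 1.0
    assert payload["BRMSEA"]["label"] in {"good", "poor"}


def test_subsample_even_coverage():
    idx = _subsample(1000, 100)
    assert idx.size == 100
    assert idx[0] == 0 and idx[-1] == 999
    assert np.all(np.diff(idx) > 0)
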