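"""Gibbs engine: diagnostics, determinism, prior sampling, contraction."""

import numpy as np
import pytest

import bcfa
from bcfa.exceptions import ValidationError
from bcfa.model import LoadingPattern


class TestPotentialScaleReduction:
    def test_identical_chains_give_one(self):
        trace = np.array([[1.0, 2.0, 3.0, 4.0]])
        psr = bcfa.potential_scale_reduction(np.vstack([trace, trace]))
        assert psr == pytest.approx(1.0)

    def test_separated_chains_explode(self):
        rng = np.random.default_rng(0)
        a = 0.0 + 0.01 * rng.standard_normal(200)
        b = 100.0 + 0.01 * rng.standard_normal(200)
        psr = bcfa.potential_scale_reduction(np.vstack([a, b]))
        assert psr > 10

    def test_hand_evaluated_two_by_four(self):
        # chains (1,2,3,4) and (2,3,4,5): W = 5/3, B = 2, var+ = 7/4
        traces = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        expected = np.sqrt((7.0 / 4.0) / (5.0 / 3.0))
        assert bcfa.potential_scale_reduction(traces) == pytest.approx(expected)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            bcfa.potential_scale_reduction(np.ones((1, 10)))


class TestCheckConvergence:
    def test_all_below_threshold(self):
        rep = bcfa.check_convergence({"a": 1.0, "b": 1.05})
        assert rep.converged

    def test_offender_named(self):
        rep = bcfa.check_convergence({"a": 1.0, "b": 1.2})
        assert not rep.converged
        assert rep.worst[0][0] == "b"

    def test_threshold_override(self):
        rep = bcfa.check_convergence({"a": 1.07}, threshold=1.05)
        assert not rep.converged


class TestSamplerContracts:
    def test_seed_determinism(self, small_two_factor_model, small_spec):
        data = bcfa.generate_continuous(small_two_factor_model, 80, seed=3)
        std = bcfa.standardize(data)
        kwargs = dict(chains=2, min_iterations=200, max_iterations=200, seed=9)
        a = bcfa.run_mcmc(small_spec, std, **kwargs)
        b = bcfa.run_mcmc(small_spec, std, **kwargs)
        np.testing.assert_array_equal(a.lam, b.lam)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_draw_validity_invariants(self, small_two_factor_model, small_spec):
        data = bcfa.generate_continuous(small_two_factor_model, 150, seed=4)
        std = bcfa.standardize(data)
        draws = bcfa.run_mcmc(small_spec, std, chains=2, min_iterations=400,
                              max_iterations=400, seed=10)
        phi = draws.flat("phi")
        np.testing.assert_allclose(phi[:, 0, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(phi, np.swapaxes(phi, 1, 2), atol=1e-12)
        assert np.all(np.abs(phi[:, 0, 1]) < 1.0)
        theta = draws.flat("theta")
        # diagonal-only spec: off-diagonals exactly zero, variances positive
        assert np.all(theta[:, np.arange(6), np.arange(6)] > 0)
        # sign alignment: summed major loadings positive in every draw
        lam = draws.flat("lam")
        for k in range(2):
            sums = lam[:, small_spec.pattern.major[:, k], k].sum(axis=1)
            assert np.all(sums > 0)

    def test_retained_count_matches_configuration(self, small_two_factor_model,
                                                  small_spec):
        data = bcfa.generate_continuous(small_two_factor_model, 80, seed=5)
        std = bcfa.standardize(data)
        draws = bcfa.run_mcmc(small_spec, std, chains=3, min_iterations=300,
                              max_iterations=300, seed=11)
        assert draws.n_chains == 3
        assert draws.n_retained == 150  # second half retained

    def test_convergence_on_well_specified_data(self, small_two_factor_model,
                                                small_spec):
        data = bcfa.generate_continuous(small_two_factor_model, 400, seed=6)
        std = bcfa.standardize(data)
        draws = bcfa.run_mcmc(small_spec, std, chains=4, min_iterations=1000,
                              max_iterations=6000, seed=12)
        assert draws.converged
        assert max(draws.psr.values()) < 1.1


@pytest.fixture(scope="module")
def prior_draws():
    major = np.zeros((4, 2), dtype=bool)
    major[:2, 0] = True
    major[2:, 1] = True
    spec = bcfa.with_crossloading_priors(
        bcfa.build_cfa_spec(LoadingPattern(major=major)), 0.01
    )
    spec = bcfa.with_residual_covariance_prior(
        spec, 10.0, np.array([0.3, 0.5, 0.7, 0.9])
    )
    return bcfa.sample_prior(spec, draws=4000, seed=21), spec


class TestPriorSampling:
    """With the likelihood switched off, the kernel samples the prior."""

    def test_crossloading_marginal_moments(self, prior_draws):
        draws, spec = prior_draws
        lam = draws.flat("lam")
        crosses = lam[:, ~spec.pattern.major]
        assert abs(crosses.mean()) < 0.01
        assert crosses.std() == pytest.approx(np.sqrt(0.01), rel=0.1)

    def test_theta_prior_mean_is_iw_mean(self, prior_draws):
        draws, spec = prior_draws
        d, d_diag = 10.0, np.array([0.3, 0.5, 0.7, 0.9])
        expected = d * np.diag(d_diag) / (d - 4 - 1)
        theta_mean = draws.flat("theta").mean(axis=0)
        np.testing.assert_allclose(theta_mean, expected, atol=0.12)

    def test_major_loading_prior_sd(self, prior_draws):
        draws, spec = prior_draws
        majors = draws.flat("lam")[:, spec.pattern.major]
        # N(0, 10) folded by the sign-alignment relabelling: check |.| moments
        assert np.mean(np.abs(majors)) == pytest.approx(
            np.sqrt(10) * np.sqrt(2 / np.pi), rel=0.1
        )


def test_posterior_contraction(small_two_factor_model, small_spec):
    """Credible intervals for major loadings shrink markedly from n=200 to n=2000."""
    widths = {}
    for n, seed in ((200, 30), (2000, 31)):
        data = bcfa.generate_continuous(small_two_factor_model, n, seed=seed)
        std = bcfa.standardize(data)
        draws = bcfa.run_mcmc(small_spec, std, chains=2, min_iterations=1500,
                              max_iterations=1500, seed=seed)
        lam = draws.flat("lam")[:, small_spec.pattern.major]
        lo, hi = np.percentile(lam, [2.5, 97.5], axis=0)
        widths[n] = hi - lo
    ratio = np.median(widths[2000] / widths[200])
    assert ratio < 0.6


def test_trace_export_naming(small_two_factor_model, small_spec):
    data = bcfa.generate_continuous(small_two_factor_model, 80, seed=7)
    std = bcfa.standardize(data)
    draws = bcfa.run_mcmc(small_spec, std, chains=2, min_iterations=100,
                          max_iterations=100, seed=13)
    frame = draws.to_frame()
    assert "lambda[q1,F1]" in frame.columns
    assert "phi[F1,F2]" in frame.columns
    assert "theta[q1,q1]" in frame.columns
    assert len(frame) == draws.n_draws
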