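"""Likelihood, prior, Metropolis–Hastings sampler and convergence diagnostics."""

import numpy as np
import pytest

from tggpp.calibrate import (
    LOG_SIGMA_BOUNDS,
    PARAM_NAMES,
    PosteriorChain,
    StuckChainError,
    calibrate_pft,
    diagnose_convergence,
    log_likelihood,
    log_prior,
    metropolis_hastings,
    split_rhat,
)
from tggpp.morris import ParamRanges
from tggpp.synthdata import recovery_preset, simulate_site
from tggpp.tg_model import TGParams, predict_gpp

from conftest import make_series


def exact_series(n=12, params=TGParams(0.0, 30.0, 50.0, m=8.0), seed=0):
    """Series whose GPP is exactly the TG prediction (zero residuals)."""
    rng = np.random.default_rng(seed)
    evi = rng.uniform(0.3, 0.8, n)
    lst = rng.uniform(5, 35, n)
    gpp = predict_gpp(evi, lst, params)
    return make_series(n=n, gpp=gpp, evi=evi, lst=lst)


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        s = exact_series(n=12)
        ll = log_likelihood([0.0, 30.0, 50.0], 0.0, s)
        assert ll == pytest.approx(-6.0 * np.log(2 * np.pi))  # ≈ −11.0272
        assert ll == pytest.approx(-11.0272, abs=1e-3)

    def test_doubling_sigma_costs_n_log2(self):
        s = exact_series(n=12)
        l1 = log_likelihood([0.0, 30.0, 50.0], 0.0, s)
        l2 = log_likelihood([0.0, 30.0, 50.0], np.log(2.0), s)
        assert l1 - l2 == pytest.approx(12 * np.log(2.0))

    def test_matches_independent_sum_of_terms(self, rng):
        """Oracle: per-month Gaussian log-density summed with scipy."""
        from scipy.stats import norm
        from tggpp.tg_model import fit_m, scale_evi, scale_lst
        s = make_series(n=36, seed=5)
        theta, log_sigma = np.array([-2.0, 24.0, 47.0]), 0.3
        d = s.valid_rows()
        p = TGParams(*theta)
        prod = scale_evi(d["evi"].to_numpy()) * scale_lst(d["lst"].to_numpy(), p)
        m = fit_m(d["gpp"].to_numpy(), prod)
        oracle = norm.logpdf(d["gpp"].to_numpy(), loc=m * prod,
                             scale=np.exp(log_sigma)).sum()
        assert log_likelihood(theta, log_sigma, s) == pytest.approx(oracle, rel=1e-12)

    def test_ordering_violation_returns_neg_inf(self):
        s = exact_series()
        assert log_likelihood([20.0, 15.0, 50.0], 0.0, s) == -np.inf


class TestLogPrior:
    def test_defaults_inside_box(self):
        assert np.isfinite(log_prior([0.0, 30.0, 50.0], 0.0))

    def test_outside_range(self):
        assert log_prior([0.0, 45.0, 50.0], 0.0) == -np.inf

    def test_ordering_violation(self):
        # x_n=20 is outside its own range too, so use a pure-ordering case
        wide = ParamRanges(x_n=(-15.0, 40.0), x_o=(10.0, 40.0), x_m=(40.0, 65.0))
        assert log_prior([20.0, 15.0, 50.0], 0.0, wide) == -np.inf

    def test_log_sigma_bounds(self):
        assert log_prior([0.0, 30.0, 50.0], LOG_SIGMA_BOUNDS[1] + 1.0) == -np.inf


class TestMetropolisHastings:
    def test_standard_normal_moments(self):
        chain = metropolis_hastings(lambda x: -0.5 * float(x @ x), [0.0],
                                    n_iter=50_000, proposal_scales=[2.4], seed=1)
        draws = chain.post_burn()[:, 0]
        assert abs(draws.mean()) < 0.05
        assert abs(draws.var(ddof=1) - 1.0) < 0.1

    def test_flat_target_fills_box_uniformly(self):
        def log_post(x):
            return 0.0 if 0.0 <= x[0] <= 1.0 else -np.inf
        chain = metropolis_hastings(log_post, [0.5], n_iter=50_000,
                                    proposal_scales=[0.25], seed=2)
        draws = chain.post_burn()[:, 0]
        for lo in (0.0, 1 / 3, 2 / 3):
            frac = np.mean((draws >= lo) & (draws < lo + 1 / 3 + 1e-12))
            assert abs(frac - 1 / 3) < 0.03

    def test_deterministic_under_seed(self):
        f = lambda x: -0.5 * float(x @ x)
        a = metropolis_hastings(f, [0.0, 0.0], 2000, [1.0, 1.0], seed=3)
        b = metropolis_hastings(f, [0.0, 0.0], 2000, [1.0, 1.0], seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_requires_finite_start(self):
        with pytest.raises(ValueError, match="finite"):
            metropolis_hastings(lambda x: -np.inf, [0.0], 100, [1.0])

    def test_stuck_chain_signalled(self):
        # target accepts nothing: -inf everywhere except the exact start
        start = np.array([0.0])
        def log_post(x):
            return 0.0 if np.array_equal(x, start) else -np.inf
        with pytest.raises(StuckChainError):
            metropolis_hastings(log_post, start, 2000, [1.0], seed=4)

    def test_acceptance_rate_in_open_interval(self):
        chain = metropolis_hastings(lambda x: -0.5 * float(x @ x), [0.0],
                                    10_000, [2.0], seed=5)
        assert 0.0 < chain.acceptance_rate < 1.0


class TestDiagnostics:
    def _chain(self, draws, names=("x_o",)):
        draws = np.atleast_2d(np.asarray(draws, float).T).T
        return PosteriorChain(names=names, samples=draws,
                              log_post=np.zeros(len(draws)), acceptance_rate=0.3,
                              burn_in=0, seed=0)

    def test_iid_normal_converged(self, rng):
        draws = rng.normal(25.0, 1.0, 20_000)
        summ = diagnose_convergence(self._chain(draws))
        s = summ.params["x_o"]
        assert s.verdict == "converged"
        assert s.median == pytest.approx(25.0, abs=0.05)
        assert s.ci_low < 25.0 < s.ci_high

    def test_uniform_prior_draws_flagged_prior_dominated(self, rng):
        draws = rng.uniform(40.0, 65.0, 20_000)
        summ = diagnose_convergence(self._chain(draws, names=("x_m",)))
        assert summ.params["x_m"].verdict == "not-converged/prior-dominated"

    def test_two_stuck_chains_not_converged(self):
        c1 = self._chain(np.full(5000, 20.0))
        c2 = self._chain(np.full(5000, 30.0))
        summ = diagnose_convergence([c1, c2])
        assert summ.params["x_o"].verdict == "not-converged"
        assert not np.isfinite(summ.params["x_o"].rhat)

    def test_split_rhat_matches_arviz(self, rng):
        """Dual route: in-package split-R̂ against the arviz implementation."""
        az = pytest.importorskip("arviz")
        draws = np.cumsum(rng.normal(size=(2, 4000)), axis=1) * 0.01 + rng.normal(size=(2, 4000))
        ours = split_rhat(draws, n_splits=4)
        theirs = float(az.rhat(az.from_dict(posterior={"x": draws}))["x"].values)
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_short_chain_raises(self):
        from tggpp.calibrate import InsufficientSamplesError
        chain = PosteriorChain(names=("x_o",), samples=np.zeros((10, 1)),
                               log_post=np.zeros(10), acceptance_rate=0.5,
                               burn_in=5, seed=0)
        with pytest.raises(InsufficientSamplesError):
            diagnose_convergence(chain)


class TestCalibratePFT:
    def test_recovers_optimum_temperature(self):
        """Short-chain smoke recovery; the full 10-seed check lives in acceptance."""
        s = simulate_site(recovery_preset(), 10, seed=1000)
        chain = calibrate_pft(s, n_iter=30_000, seed=2000)
        assert chain.names == PARAM_NAMES
        med = np.median(chain.post_burn(), axis=0)
        assert med[1] == pytest.approx(25.0, abs=2.5)
        # every retained sample respects ordering and the prior box
        d = chain.post_burn()
        assert np.all((d[:, 0] < d[:, 1]) & (d[:, 1] < d[:, 2]))
        assert d[:, 1].min() >= 10.0 and d[:, 1].max() <= 40.0
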