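import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from skystruct import (
    ChainSettings,
    SkylineFunction,
    bayesian_skyline,
    classic_skyline,
    coalescent_loglik,
    psc_mean,
)
from skystruct.skyline import PscPrior, SkylinePosterior, _CoalData
from tests.conftest import make_genealogy


class TestClassicSkyline:
    def test_two_tips(self):
        fn = classic_skyline(make_genealogy([500.0]))
        assert fn.sizes == pytest.approx([500.0])

    def test_three_tips(self):
        # tau_3 = 100 with C(3,2) = 3; tau_2 = 300 with C(2,2) = 1
        fn = classic_skyline(make_genealogy([100.0, 400.0]))
        assert fn.sizes == pytest.approx([300.0, 300.0])
        assert fn.boundaries == pytest.approx([0.0, 100.0, 400.0])

    def test_unbiased_per_interval_under_constant_size(self):
        """E[tau_k * C(k,2)] = N for every k in a constant panmictic population."""
        from skystruct import SamplingScheme, StructuredModel, simulate_genealogy

        N = 800.0
        model = StructuredModel(deme_sizes=np.array([N]), migration=np.zeros((1, 1)))
        scheme = SamplingScheme("local", {0: 5}, 5)
        rng = np.random.default_rng(41)
        per_interval = np.array(
            [classic_skyline(simulate_genealogy(model, scheme, rng)).sizes
             for _ in range(1000)]
        )
        means = per_interval.mean(axis=0)
        ses = per_interval.std(axis=0, ddof=1) / math.sqrt(len(per_interval))
        assert np.all(np.abs(means - N) < 3.5 * ses)


class TestCoalescentLoglik:
    def test_two_tip_closed_form(self):
        g = make_genealogy([500.0])
        fn = SkylineFunction(boundaries=np.array([0.0, 500.0]), sizes=np.array([1000.0]))
        assert coalescent_loglik(g, fn) == pytest.approx(math.log(1 / 1000) - 0.5)

    def test_constant_mle_matches_analytic(self):
        g = make_genealogy([120.0, 340.0, 900.0, 1500.0])
        times = g.coalescence_times()
        n = g.n_tips
        ks = np.arange(n, 1, -1)
        tau = np.diff(np.concatenate([[0.0], times]))
        analytic = float(np.sum(ks * (ks - 1) / 2 * tau) / (n - 1))

        def neg(logN):
            fn = SkylineFunction(np.array([0.0, 1500.0]), np.array([math.exp(logN)]))
            return -coalescent_loglik(g, fn)

        res = minimize_scalar(neg, bounds=(0, 20), method="bounded")
        assert math.exp(res.x) == pytest.approx(analytic, rel=1e-5)

    def test_scale_equivariance(self):
        g = make_genealogy([100.0, 400.0])
        g2 = make_genealogy([200.0, 800.0])
        fn = SkylineFunction(np.array([0.0, 400.0]), np.array([300.0]))
        fn2 = SkylineFunction(np.array([0.0, 800.0]), np.array([600.0]))
        # doubling all sizes and times changes the density by -(n-1) ln 2
        assert coalescent_loglik(g2, fn2) == pytest.approx(
            coalescent_loglik(g, fn) - 2 * math.log(2)
        )

    def test_coverage_required(self):
        g = make_genealogy([100.0, 400.0])
        fn = SkylineFunction(np.array([0.0, 200.0]), np.array([300.0]))
        with pytest.raises(ValueError):
            coalescent_loglik(g, fn)


class TestPriorRecovery:
    def test_prior_only_psc_is_poisson_ln2(self):
        g = make_genealogy(np.linspace(100, 4000, 39).tolist())
        rng = np.random.default_rng(43)
        chain = ChainSettings(n_steps=120_000, thin=100, prior_only=True)
        post = bayesian_skyline(g, rng, chain=chain)
        draws = post.psc_samples
        # P(PSC = 0) = exp(-ln 2) = 0.5: zero change and any change equally likely
        assert abs(np.mean(draws == 0) - 0.5) < 0.05
        lam = math.log(2)
        kmax = 3
        obs = np.array([np.sum(draws == k) for k in range(kmax)] + [np.sum(draws >= kmax)])
        pk = np.array([stats.poisson.pmf(k, lam) for k in range(kmax)]
                      + [1 - stats.poisson.cdf(kmax - 1, lam)])
        res = stats.chisquare(obs, pk * len(draws))
        assert res.pvalue > 0.01

    def test_prior_only_sizes_are_log_uniform(self):
        g = make_genealogy(np.linspace(100, 2000, 19).tolist())
        rng = np.random.default_rng(44)
        chain = ChainSettings(n_steps=60_000, thin=60, prior_only=True)
        post = bayesian_skyline(g, rng, chain=chain)
        logs = np.log([sizes[0] for _, sizes in post.samples])
        lo, hi = chain.size_bounds
        u = (logs - math.log(lo)) / (math.log(hi) - math.log(lo))
        assert stats.kstest(u, "uniform").pvalue > 0.005


class TestPosterior:
    def test_psc_mean(self):
        def mk(draws):
            z = np.zeros(1)
            return SkylinePosterior([], np.asarray(draws, int), z, z, z, z, 100.0,
                                    False, 0.3)

        assert psc_mean(mk([0, 0, 0, 0])) == 0.0
        assert psc_mean(mk([0, 1, 2, 1])) == 1.0
        with pytest.raises(ValueError):
            psc_mean(mk([]))

    def test_hpd_contains_median_and_grid_consistency(self):
        g = make_genealogy(np.linspace(50, 3000, 14).tolist())
        rng = np.random.default_rng(45)
        post = bayesian_skyline(g, rng, chain=ChainSettings(n_steps=20_000, thin=20))
        assert np.all(post.hpd_lo <= post.median_curve + 1e-9)
        assert np.all(post.median_curve <= post.hpd_hi + 1e-9)
        # median at t = 0 equals the median of most-recent-segment sizes
        recent = np.array([sizes[0] for _, sizes in post.samples])
        assert post.median_curve[0] == pytest.approx(np.median(recent))
        assert post.grid[0] == 0.0
        assert post.grid[-1] == pytest.approx(g.root_time)

    def test_matches_numerical_integration_oracle(self):
        """On a 3-tip genealogy the model-averaged posterior (0 or 1 change
        point at the first coalescence) is a sum of 1-D integrals; the MCMC
        must agree on P(PSC = 0) and E[log N(0)]."""
        g = make_genealogy([100.0, 400.0])
        lo, hi = 1.0, 1e8
        logn = np.linspace(math.log(lo), math.log(hi), 40_001)
        N = np.exp(logn)
        log_range = math.log(hi / lo)
        prior = 1.0 / log_range  # density in log N

        def integrate(f):
            return np.trapezoid(f, logn)

        lam = math.log(2)
        # config k=0: one size covering both intervals; A_tot = 600, 2 coalescences
        post0 = np.exp(-600.0 / N) * N**-2 * prior
        w0 = stats.poisson.pmf(0, lam) * integrate(post0)
        # config k=1: segments split at t=100; each has A = 300 and 1 coalescence
        seg = np.exp(-300.0 / N) * N**-1 * prior
        w1 = stats.poisson.pmf(1, lam) * integrate(seg) ** 2
        p0_expected = w0 / (w0 + w1)
        elog0_k0 = integrate(logn * post0) / integrate(post0)
        elog0_k1 = integrate(logn * seg) / integrate(seg)
        elog0_expected = p0_expected * elog0_k0 + (1 - p0_expected) * elog0_k1

        rng = np.random.default_rng(46)
        post = bayesian_skyline(g, rng, chain=ChainSettings(n_steps=200_000, thin=20))
        p0_mcmc = float(np.mean(post.psc_samples == 0))
        elog0_mcmc = float(np.mean(np.log([s[0] for _, s in post.samples])))
        assert abs(p0_mcmc - p0_expected) < 0.05
        assert abs(elog0_mcmc - elog0_expected) < 0.25

    def test_multilocus_pooling_tightens_inference(self):
        """Pooled independent genealogies share one demography; more loci give
        narrower HPDs around the true constant size."""
        from skystruct import SamplingScheme, StructuredModel, simulate_genealogy

        model = StructuredModel(deme_sizes=np.array([1000.0]), migration=np.zeros((1, 1)))
        scheme = SamplingScheme("local", {0: 10}, 10)
        rng = np.random.default_rng(47)
        gs = [simulate_genealogy(model, scheme, rng) for _ in range(8)]
        one = bayesian_skyline(gs[0], np.random.default_rng(1),
                               chain=ChainSettings(n_steps=20_000, thin=20))
        many = bayesian_skyline(gs, np.random.default_rng(2),
                                chain=ChainSettings(n_steps=20_000, thin=20))
        width_one = np.log(one.hpd_hi[0] / one.hpd_lo[0])
        width_many = np.log(many.hpd_hi[0] / many.hpd_lo[0])
        assert width_many < width_one


def test_sufficient_statistics_match_direct_likelihood():
    """The interpolated-A likelihood equals a brute-force interval sum."""
    g = make_genealogy([120.0, 340.0, 900.0])
    fn = SkylineFunction(np.array([0.0, 200.0, 900.0]), np.array([250.0, 700.0]))
    # brute force: iterate sub-intervals between all breakpoints
    events = g.coalescence_times()
    edges = np.unique(np.concatenate([[0.0], events, fn.boundaries]))
    ll = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        k = g.n_tips - np.searchsorted(events, a, side="right")
        Nv = fn.at(0.5 * (a + b))
        ll -= k * (k - 1) / 2 * (b - a) / Nv
        if np.any(np.isclose(events, b)):
            ll += math.log(k * (k - 1) / 2.0 / Nv)
    assert coalescent_loglik(g, fn) == pytest.approx(ll)
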