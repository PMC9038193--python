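"""Baseline bias, scaling factors, site probabilities, likelihood and cost."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from cachechoice import (
    ParameterVector,
    compute_mask,
    compute_pbias,
    derive_state,
    log_scaling_factors,
    site_probabilities,
)
from cachechoice.choice import (
    LN10,
    BiasDistribution,
    LikelihoodData,
    ZeroProbabilityError,
    cost,
    log_likelihood,
    ridge_penalty,
    state_at,
)

from conftest import make_dataset
from oracles import brute_force_log_likelihood


def uniform_bias(arena, cache_only=True):
    p = arena.is_cache_site.astype(float) if cache_only else np.ones(arena.n_sites)
    return BiasDistribution(p / p.sum())


def empty_state(arena, prev=-1, occupied=(), checked_empty=(), recache=()):
    S = arena.n_sites
    occ = np.zeros(S)
    occ[list(occupied)] = 1
    ce = np.zeros(S)
    ce[list(checked_empty)] = 1
    rec = np.zeros(S)
    rec[list(recache)] = 1
    t = np.where(occ + ce > 0, 60.0, np.inf)
    from cachechoice.choice import EventState

    return EventState(
        prev_site=prev,
        occupancy=occ,
        checked_empty=ce,
        recache=rec,
        time_since=t,
        total_occupancy=occ.sum(),
        total_checked_empty=ce.sum(),
    )


class TestPbias:
    def test_single_support_point(self, arena):
        ds = make_dataset([(0, 0, 0, float(t), 5, 1) for t in range(1, 4)])
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "caches_caching")
        pb = compute_pbias(ds, m, arena.n_sites)
        assert pb.p[5] == 1.0
        assert pb.p.sum() == pytest.approx(1.0)

    def test_hand_counted_frequencies(self, arena):
        ds = make_dataset(
            [(0, 0, 0, float(t), s, 1) for t, s in enumerate([1, 1, 2, 3], 1)]
        )
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "caches_caching")
        pb = compute_pbias(ds, m, arena.n_sites)
        assert pb.p[1] == pytest.approx(0.5)
        assert pb.p[2] == pytest.approx(0.25)
        assert pb.p[3] == pytest.approx(0.25)

    def test_empty_mask_errors(self, arena):
        ds = make_dataset([(0, 0, 0, 1.0, 5, 0)])  # a check, not a cache
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "caches_caching")
        with pytest.raises(ValueError, match="empty mask"):
            compute_pbias(ds, m, arena.n_sites)


class TestScalingFactors:
    def test_zero_theta_zero_alpha(self, arena):
        st = empty_state(arena, prev=3, occupied=[7], checked_empty=[9])
        a = log_scaling_factors(st, ParameterVector(), arena)
        assert np.all(a == 0)

    def test_previous_site_itself_excluded(self, arena):
        st = empty_state(arena, prev=3)
        theta = ParameterVector(gamma_prv=5.0, sigma_prv=10.0)
        a = log_scaling_factors(st, theta, arena)
        assert a[0, 3] == 0.0
        assert a[0, 2] > 0  # neighbors are boosted

    def test_site_local_occupied_factor(self, arena):
        # one occupied site, sigma -> 0, no decays: alpha2 = gamma at the
        # site and 0 elsewhere (a tenfold decrease at the cache itself)
        st = empty_state(arena, occupied=[7])
        theta = ParameterVector(gamma_occ=-1.0, sigma_occ=0.0)
        a = log_scaling_factors(st, theta, arena)
        assert a[1, 7] == pytest.approx(-1.0)
        assert np.all(a[1, np.arange(arena.n_sites) != 7] == 0)

    def test_gaussian_sums_over_occupied_sites(self, arena):
        st = empty_state(arena, occupied=[0, 1])
        theta = ParameterVector(gamma_occ=1.0, sigma_occ=7.1)
        a = log_scaling_factors(st, theta, arena)
        D = arena.distance_matrix()
        expected = sum(np.exp(-D[sp] ** 2 / (2 * 7.1**2)) for sp in (0, 1))
        assert a[1] == pytest.approx(expected)

    def test_capacity_and_time_decay(self, arena):
        st = empty_state(arena, occupied=[7])  # t = 60 s at the site
        theta = ParameterVector(
            gamma_occ=1.0, sigma_occ=0.0, inv_tau_occ=1 / 120.0, inv_nu_occ=0.5
        )
        a = log_scaling_factors(st, theta, arena)
        assert a[1, 7] == pytest.approx(np.exp(-60 / 120) * np.exp(-1 * 0.5))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma_prv"):
            ParameterVector(sigma_prv=-1.0)

    def test_recache_split(self, arena):
        st = empty_state(arena, occupied=[3, 4], recache=[4])
        theta = ParameterVector(gamma_occc=0.3, gamma_occr=0.7)
        a = log_scaling_factors(st, theta, arena)
        assert a[4, 3] == pytest.approx(0.3)   # old cache
        assert a[3, 4] == pytest.approx(0.7)   # recache
        assert a[4, 4] == 0.0


class TestSiteProbabilities:
    def test_zero_theta_returns_pbias(self, arena):
        pb = uniform_bias(arena)
        st = empty_state(arena, prev=3, occupied=[7])
        dist = site_probabilities(st, ParameterVector(), pb, arena)
        assert dist.p_hat == pytest.approx(pb.p)

    def test_closed_form_single_occupied_site(self, arena):
        # uniform bias over 64 sites, one occupied site at gamma = -1:
        # that site keeps 0.1 of its weight -> (1/10) / (63 + 1/10)
        pb = uniform_bias(arena)
        st = empty_state(arena, occupied=[7])
        theta = ParameterVector(gamma_occ=-1.0, sigma_occ=0.0)
        dist = site_probabilities(st, theta, pb, arena)
        assert dist.p_hat[7] == pytest.approx(0.1 / (63 + 0.1))

    def test_checked_empty_fold_change(self, arena):
        # gamma_emp = 0.13 multiplies the unnormalized probability of a
        # checked-empty site by 10^0.13, about 1.3
        pb = uniform_bias(arena)
        st = empty_state(arena, checked_empty=[5])
        theta = ParameterVector(gamma_emp=0.13, sigma_emp=0.0)
        dist = site_probabilities(st, theta, pb, arena)
        ratio = dist.p_unnormalized[5] / dist.p_unnormalized[6]
        assert ratio == pytest.approx(10**0.13)
        assert ratio == pytest.approx(1.35, abs=0.01)

    def test_normalization(self, arena):
        rng = np.random.default_rng(0)
        pb = BiasDistribution(rng.dirichlet(np.ones(arena.n_sites)))
        for _ in range(10):
            theta = ParameterVector(
                gamma_prv=rng.uniform(-2, 2),
                sigma_prv=rng.uniform(0, 30),
                gamma_occ=rng.uniform(-2, 2),
                sigma_occ=rng.uniform(0, 30),
                gamma_emp=rng.uniform(-2, 2),
            )
            st = empty_state(
                arena, prev=int(rng.integers(64)),
                occupied=rng.choice(64, 5, replace=False),
                checked_empty=rng.choice(np.arange(5, 30), 4, replace=False),
            )
            st.checked_empty *= 1 - st.occupancy
            dist = site_probabilities(st, theta, pb, arena)
            assert dist.p_hat.sum() == pytest.approx(1.0)
            assert np.all(dist.p_hat[pb.p == 0] == 0)

    def test_monotone_in_gamma_occ(self, arena):
        pb = uniform_bias(arena)
        st = empty_state(arena, occupied=[7])
        last = 0.0
        for g in [0.1, 0.5, 1.0, 2.0]:
            theta = ParameterVector(gamma_occ=g, sigma_occ=0.0)
            p = site_probabilities(st, theta, pb, arena).p_hat[7]
            assert p > last
            last = p

    def test_all_zero_vector_errors(self, arena):
        pb = BiasDistribution(np.eye(arena.n_sites)[3])
        st = empty_state(arena, occupied=[3])
        theta = ParameterVector(gamma_occ=-10.0, sigma_occ=0.0)
        # site 3 carries all bias mass but is suppressed by 10 decades;
        # the result is still normalizable (tiny but positive)
        dist = site_probabilities(st, theta, pb, arena)
        assert dist.p_hat[3] == pytest.approx(1.0)


class TestLikelihood:
    def test_single_event_uniform(self, arena):
        ds = make_dataset([(0, 0, 0, 1.0, 5, 1)])
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "caches_caching")
        pb = uniform_bias(arena, cache_only=False)  # all 68 sites
        L = log_likelihood(ds, ParameterVector(), m, pb, arena, state=st)
        assert L == pytest.approx(np.log(1 / 68))

    def test_empty_mask_zero(self, arena, toy_dataset):
        st = derive_state(toy_dataset, arena)
        m = compute_mask(toy_dataset, st, "checks_closed")  # no phase-2 events
        pb = uniform_bias(arena)
        assert log_likelihood(toy_dataset, ParameterVector(), m, pb, arena) == 0.0

    def test_two_event_brute_force(self, arena, toy_dataset):
        st = derive_state(toy_dataset, arena)
        m = compute_mask(toy_dataset, st, "caches_caching")
        pb = compute_pbias(toy_dataset, m, arena.n_sites)
        theta = ParameterVector(
            gamma_prv=0.8, sigma_prv=12.0, gamma_occ=-0.5, gamma_emp=0.2
        )
        L = log_likelihood(toy_dataset, theta, m, pb, arena, state=st)
        oracle = brute_force_log_likelihood(toy_dataset, st, m, pb, arena, theta)
        assert L == pytest.approx(oracle, abs=1e-10)

    def test_zero_bias_site_raises_and_floors(self, arena):
        # the first check after the feeder visit lands on site 20, which
        # never receives a cache and so has zero cache-derived bias
        ds = make_dataset(
            [
                (0, 0, 0, 1.0, 64, -1),
                (0, 0, 0, 3.0, 20, 0),
                (0, 0, 0, 5.0, 3, 1),
            ]
        )
        st = derive_state(ds, arena)
        m = compute_mask(ds, st, "first_checks_caching")
        assert list(np.flatnonzero(m.H)) == [1]
        pb = compute_pbias(
            ds, compute_mask(ds, st, "caches_caching"), arena.n_sites
        )
        with pytest.raises(ZeroProbabilityError):
            LikelihoodData(ds, st, m, pb, arena)
        data = LikelihoodData(ds, st, m, pb, arena, on_zero="floor")
        assert np.isfinite(data.log_likelihood(ParameterVector()))

    def test_decay_limits_reduce_to_pure_gaussian(self, arena, caching_bird):
        st = derive_state(caching_bird, arena)
        m = compute_mask(caching_bird, st, "caches_caching")
        pb = compute_pbias(caching_bird, m, arena.n_sites)
        base = ParameterVector(gamma_occ=-0.5, sigma_occ=10.0, gamma_emp=0.3)
        off = base.replace(inv_tau_occ=0.0, inv_nu_occ=0.0)
        L1 = log_likelihood(caching_bird, base, m, pb, arena, state=st)
        L2 = log_likelihood(caching_bird, off, m, pb, arena, state=st)
        assert L1 == pytest.approx(L2)  # base already has zero inverses

    def test_gradient_matches_finite_differences(self, arena, caching_bird):
        st = derive_state(caching_bird, arena)
        m = compute_mask(caching_bird, st, "caches_caching")
        pb = compute_pbias(caching_bird, m, arena.n_sites)
        data = LikelihoodData(caching_bird, st, m, pb, arena)
        theta = ParameterVector(
            gamma_prv=0.5, sigma_prv=10.0, gamma_occ=-0.2, sigma_occ=5.0,
            gamma_emp=0.1, sigma_emp=3.0, gamma_occc=0.1, gamma_occr=0.05,
            inv_tau_occ=1e-3, inv_tau_emp=2e-3, inv_nu_occ=0.05,
            inv_nu_emp=0.03,
        )
        _, g = data.log_likelihood_and_grad(theta)
        gn = approx_fprime(
            theta.to_array(),
            lambda x: data.log_likelihood(ParameterVector.from_array(x)),
            1e-6,
        )
        assert g == pytest.approx(gn, rel=1e-3, abs=1e-3)


class TestCost:
    def test_zero_theta_no_penalty(self, arena, caching_bird):
        st = derive_state(caching_bird, arena)
        m = compute_mask(caching_bird, st, "caches_caching")
        pb = compute_pbias(caching_bird, m, arena.n_sites)
        data = LikelihoodData(caching_bird, st, m, pb, arena)
        theta = ParameterVector()
        assert cost(data, theta, 1.0) == pytest.approx(
            -data.log_likelihood(theta)
        )

    def test_penalty_arithmetic(self, arena, caching_bird):
        st = derive_state(caching_bird, arena)
        m = compute_mask(caching_bird, st, "caches_caching")
        pb = compute_pbias(caching_bird, m, arena.n_sites)
        data = LikelihoodData(caching_bird, st, m, pb, arena)
        theta = ParameterVector(gamma_prv=2.0)
        assert cost(data, theta, 1.0) == pytest.approx(
            -data.log_likelihood(theta) + 4.0
        )
        assert ridge_penalty(theta, 1.0) == 4.0

    def test_pooled_cost_single_penalty(self, arena, caching_bird, toy_dataset):
        st1 = derive_state(caching_bird, arena)
        m1 = compute_mask(caching_bird, st1, "caches_caching")
        pb1 = compute_pbias(caching_bird, m1, arena.n_sites)
        d1 = LikelihoodData(caching_bird, st1, m1, pb1, arena)
        st2 = derive_state(toy_dataset, arena)
        m2 = compute_mask(toy_dataset, st2, "caches_caching")
        pb2 = compute_pbias(toy_dataset, m2, arena.n_sites)
        d2 = LikelihoodData(toy_dataset, st2, m2, pb2, arena)
        theta = ParameterVector(gamma_prv=1.0, gamma_occ=-0.5)
        pooled = cost([d1, d2], theta, 2.0)
        expected = (
            -d1.log_likelihood(theta)
            - d2.log_likelihood(theta)
            + 2.0 * (1.0 + 0.25)
        )
        assert pooled == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            ridge_penalty(ParameterVector(), -1.0)
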