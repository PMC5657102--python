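"""Field potentials, forward/backward vs path enumeration, EM updates, ICM."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.special import expit

from burdenmrf import (Dataset, GenotypeMatrix, HMRFConfig, SimConfig,
                       em_update_mu, em_update_pb, em_update_theta, f_func,
                       fit, forward_backward_R, generate_dataset,
                       region_potential, site_evidence, trans_H, trans_J,
                       xi_pairwise)
from burdenmrf.hmrf import (_region_transition, _theta_objective,
                            carrier_error_posterior, icm_update_X,
                            parity_emissions)


def brute_force_posteriors(emissions, trans, prior):
    """Exact per-site and pairwise posteriors by full path enumeration."""
    e = np.asarray(emissions, float)
    m, s = e.shape
    tr = np.asarray(trans, float)
    if tr.ndim == 2:
        tr = np.broadcast_to(tr, (m - 1, s, s))
    gamma = np.zeros((m, s))
    xi = np.zeros((max(m - 1, 0), s, s))
    total = 0.0
    for path in itertools.product(range(s), repeat=m):
        w = prior[path[0]] * e[0, path[0]]
        for t in range(1, m):
            w *= tr[t - 1, path[t - 1], path[t]] * e[t, path[t]]
        total += w
        for t in range(m):
            gamma[t, path[t]] += w
        for t in range(m - 1):
            xi[t, path[t], path[t + 1]] += w
    return gamma / total, xi / total, np.log(total)


def random_chain(rng, m, s=2):
    e = rng.random((m, s)) + 0.05
    tr = rng.random((m - 1, s, s)) + 0.05
    tr /= tr.sum(axis=2, keepdims=True)
    prior = rng.random(s) + 0.05
    prior /= prior.sum()
    return e, tr, prior


class TestPotentials:
    def test_f_func_values(self):
        assert f_func(0.0, 10) == 0.0
        assert f_func(1.0, 4) == pytest.approx((1 - np.exp(-1)) / 4)
        assert f_func(1e9, 4) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            f_func(1.0, 0)

    def test_trans_h_saturates_at_mu_one(self):
        vals = {trans_H(1.0, th, d, same, 5)
                for th in (0.5, 2.0) for d in (0.5, 2.0)
                for same in (True, False)}
        assert len(vals) == 1  # pure-mutation: independent of theta, d, I

    def test_trans_h_zero_distance_matches_limit(self):
        at_zero = trans_H(0.01, 1.0, 0.0, True, 8)
        near_zero = trans_H(0.01, 1.0, 1e-10, True, 8)
        assert at_zero == pytest.approx(near_zero, rel=1e-6)

    def test_trans_h_agreement_dominates(self):
        for mu in (0.0, 0.2, 0.9):
            for th in (0.1, 1.0, 5.0):
                for d in (0.1, 1.0, 3.0):
                    assert (trans_H(mu, th, d, True, 6)
                            >= trans_H(mu, th, d, False, 6))

    def test_trans_j_zero_distance(self):
        assert trans_J(1.0, 0.0, 10) == (1.0, 0.0)

    def test_trans_j_large_distance_channels(self):
        dup, perm = trans_J(2.0, 10.0, 10)
        # f(-theta d) is very negative: both channels clip to 0
        assert dup == 0.0 and perm == 0.0
        # pre-clip identity: the permutation channel sums to f(-theta d)
        assert (10 - 1) * (f_func(-2.0 * 10.0, 10) / (10 - 1)) == \
            pytest.approx(f_func(-20.0, 10))

    def test_region_potential_examples(self):
        # symmetric null: no preference
        assert region_potential(0.0, [], [], 0.5, 0.5) == 1.0
        # two-site toy: exp(0.5 log 1.5 + 0.5)
        b = np.log(0.6 / 0.4)
        val = region_potential(b, [1.0], [1.0], 0.5, 0.5)
        assert val == pytest.approx(np.exp(0.5 * np.log(1.5) + 0.5),
                                    rel=1e-9)

    def test_region_potential_decoupled_monotone_in_pe(self):
        vals = [region_potential(np.log(p / (1 - p)), [1.0], [1.0],
                                 1.0, 0.0) for p in (0.3, 0.5, 0.8)]
        assert vals[0] < vals[1] < vals[2]


class TestForwardBackward:
    def test_single_site_posterior_is_normalized_prior_times_emission(self):
        e = np.array([[0.2, 0.6]])
        prior = np.array([0.5, 0.5])
        tab = forward_backward_R(e, np.empty((0, 2, 2)), prior)
        expected = e[0] * prior / (e[0] * prior).sum()
        np.testing.assert_allclose(tab.gamma[0], expected, atol=1e-12)

    def test_uniform_chain_gives_uniform_posteriors(self):
        e = np.ones((5, 2))
        tr = np.full((2, 2), 0.5)
        tab = forward_backward_R(e, tr, np.array([0.5, 0.5]))
        np.testing.assert_allclose(tab.gamma, 0.5, atol=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_matches_path_enumeration(self, rng, m):
        e, tr, prior = random_chain(rng, m)
        tab = forward_backward_R(e, tr, prior)
        gamma, xi, loglik = brute_force_posteriors(e, tr, prior)
        np.testing.assert_allclose(tab.gamma, gamma, atol=1e-10)
        np.testing.assert_allclose(tab.xi, xi, atol=1e-10)
        assert tab.loglik == pytest.approx(loglik, abs=1e-10)

    def test_three_state_chain_against_enumeration(self, rng):
        e, tr, prior = random_chain(rng, 4, s=3)
        tab = forward_backward_R(e, tr, prior)
        gamma, xi, _ = brute_force_posteriors(e, tr, prior)
        np.testing.assert_allclose(tab.gamma, gamma, atol=1e-10)
        np.testing.assert_allclose(tab.xi, xi, atol=1e-10)

    def test_posterior_and_xi_normalization(self, rng):
        e, tr, prior = random_chain(rng, 50)
        tab = forward_backward_R(e, tr, prior)
        np.testing.assert_allclose(tab.gamma.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(tab.xi.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_xi_marginal_recovers_site_posterior(self, rng):
        e, tr, prior = random_chain(rng, 6)
        tab = forward_backward_R(e, tr, prior)
        np.testing.assert_allclose(tab.xi.sum(axis=2), tab.gamma[:-1],
                                   atol=1e-9)
        np.testing.assert_allclose(tab.xi.sum(axis=1), tab.gamma[1:],
                                   atol=1e-9)

    def test_deterministic_chain_xi_is_point_mass(self):
        e = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        tr = np.array([[0.5, 0.5], [0.5, 0.5]])
        tab = forward_backward_R(e, np.broadcast_to(tr, (2, 2, 2)),
                                 np.array([0.5, 0.5]))
        assert tab.xi[0, 0, 0] == pytest.approx(1.0)
        assert tab.xi[1, 0, 1] == pytest.approx(1.0)

    def test_degenerate_emissions_raise(self):
        e = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(FloatingPointError):
            forward_backward_R(e, np.full((2, 2), 0.5),
                               np.array([0.5, 0.5]))

    def test_parity_emission_layout(self):
        pb = np.array([0.7, 0.2])
        pe = 1 - pb
        rx = np.ones((2, 4))
        e = parity_emissions(pb, pe, rx)
        np.testing.assert_allclose(e[:, 0], pb)
        np.testing.assert_allclose(e[:, 2], pb)
        np.testing.assert_allclose(e[:, 1], pe)
        np.testing.assert_allclose(e[:, 3], pe)
        with pytest.raises(ValueError):
            parity_emissions(pb, pe, np.ones((2, 3)))


class TestEMUpdates:
    def test_mu_zero_when_hidden_equals_observed(self):
        g = np.array([[1, 0], [0, 2]])
        assert em_update_mu(g, g, np.ones_like(g, float)) == 0.0

    def test_mu_hand_computed_toy(self):
        g = np.array([[1, 0], [1, 1]])
        h = np.array([[1, 0], [0, 1]])  # one disagreement at a carrier
        w = np.array([[0.5, 0.25], [0.8, 0.4]])
        # num = I(h != g) w = 0.8 ; denom = I(g > 0) w = 0.5 + 0.8 + 0.4
        assert em_update_mu(h, g, w) == pytest.approx(0.8 / 1.7)

    def test_mu_scale_invariant(self):
        g = np.array([[1, 0], [1, 1]])
        h = np.array([[1, 0], [0, 1]])
        w = np.array([[0.5, 0.25], [0.8, 0.4]])
        assert em_update_mu(h, g, w) == em_update_mu(h, g, 2 * w)

    def test_mu_all_reference_raises(self):
        z = np.zeros((2, 2))
        with pytest.raises(ZeroDivisionError):
            em_update_mu(z, z, np.ones((2, 2)))

    def test_theta_matches_grid_search_oracle(self, rng):
        true_theta = 1.2
        tr = _region_transition(0.01, true_theta, 1.0, 50)
        # xi built from exact transition frequencies of a long chain
        stationary = np.array([0.5, 0.5])
        joint = stationary[:, None] * tr
        xi = np.broadcast_to(joint, (400, 2, 2)).copy()
        d = np.ones(400)
        got = em_update_theta(xi, d, 0.01, 50, bounds=(1e-3, 50.0))
        grid = np.exp(np.linspace(np.log(1e-3), np.log(50.0), 4000))
        vals = [_theta_objective(t, xi, d, 0.01, 50) for t in grid]
        best_grid = grid[int(np.argmax(vals))]
        assert (_theta_objective(got, xi, d, 0.01, 50)
                >= max(vals) - 1e-6)
        assert np.isclose(np.log(got), np.log(best_grid), atol=0.05)

    def test_theta_recovery_from_generated_chains(self, rng):
        """Chains simulated at a known theta yield an estimate whose
        sampling distribution covers the truth (parameter recovery)."""
        true_theta = 1.0
        n = 50
        tr = _region_transition(0.01, true_theta, 1.0, n)
        ests = []
        for _ in range(15):
            states = [0]
            for _ in range(800):
                states.append(rng.choice(2, p=tr[states[-1]]))
            s = np.asarray(states)
            xi = np.zeros((len(s) - 1, 2, 2))
            xi[np.arange(len(s) - 1), s[:-1], s[1:]] = 1.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ests.append(em_update_theta(xi, np.ones(len(s) - 1),
                                            0.01, n))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(np.median(ests) - true_theta) < max(3 * se, 0.5)

    def test_theta_degenerate_chain_warns_and_returns_bound(self):
        with pytest.warns(UserWarning):
            got = em_update_theta(np.empty((0, 2, 2)), np.ones(1), 0.01, 10,
                                  bounds=(1e-3, 50.0))
        assert got == 1e-3

    def test_pb_literal_zero_distance_denominator_one(self):
        xi = np.zeros((1, 2, 2))
        xi[0, 0, 0] = 0.6
        xi[0, 1, 1] = 0.4
        pb, pe = em_update_pb(xi, 2.0, np.zeros(1), 100)
        assert pb[0] == pytest.approx(0.6)  # denominator exactly 1 at d=0
        np.testing.assert_allclose(pb + pe, 1.0)

    def test_pb_boundary_clipping(self):
        xi = np.zeros((1, 2, 2))  # xi(0,0) = 0 -> P^b at the eps floor
        xi[0, 1, 1] = 1.0
        pb, pe = em_update_pb(xi, 1.0, np.ones(1), 100, eps=1e-3)
        assert pb[0] == pytest.approx(1e-3)
        assert pe[0] == pytest.approx(1 - 1e-3)

    def test_pb_normalized_mode_is_diagonal_ratio(self):
        xi = np.zeros((1, 2, 2))
        xi[0, 0, 0] = 0.3
        xi[0, 1, 1] = 0.1
        pb, _ = em_update_pb(xi, 1.0, np.ones(1), 100, normalize=True)
        assert pb[0] == pytest.approx(0.75)


def separable_dataset(n_arm=250, n_strong=30, n_weak=10, carriers=12,
                      seed=3):
    """Strong case-only signal at the first sites, control-only at the rest.

    Strong sites share one carrier set (mutually compatible, omega = 1);
    weak sites carry in controls only.
    """
    rng = np.random.default_rng(seed)
    m = n_strong + n_weak
    n = 2 * n_arm
    g = np.zeros((n, m), dtype=np.int8)
    labels = np.concatenate([np.ones(n_arm, np.int8),
                             np.zeros(n_arm, np.int8)])
    g[:carriers, :n_strong] = 1              # cases 0..carriers-1
    g[n_arm:n_arm + 3, n_strong:] = 1        # a few control carriers
    mafs = np.full(m, 0.01)
    return Dataset(genotypes=GenotypeMatrix(g), labels=labels,
                   causal_truth=np.concatenate([np.ones(n_strong, np.int8),
                                                np.zeros(n_weak, np.int8)]),
                   control_mafs=mafs, case_mafs=mafs.copy())


class TestICMAndFit:
    def test_separable_fixture_selects_case_only_sites(self):
        ds = separable_dataset()
        fitted = fit(ds)
        sel = set(fitted.selected.tolist())
        assert set(range(30)) <= sel
        assert not sel & set(range(30, 40))

    def test_single_site_matches_marginal_sign(self):
        cfg = HMRFConfig()
        omega = np.zeros((1, 1))
        q = np.array([0.9])
        strong = np.array([5.0])   # above any threshold
        weak = np.array([-1.0])
        assert icm_update_X(np.array([0]), strong, omega, q, cfg)[0] == 1
        assert icm_update_X(np.array([1]), weak, omega, q, cfg)[0] == 0

    def test_null_par_selection_collapses(self):
        cfg = SimConfig(group_par=0.0, seed=17)
        ds = generate_dataset(cfg, np.random.default_rng(17))
        fitted = fit(ds)
        assert fitted.selected.size <= 2

    def test_fit_is_deterministic(self, small_dataset):
        a = fit(small_dataset, cfg=HMRFConfig(evidence_mass_ref=5.0))
        b = fit(small_dataset, cfg=HMRFConfig(evidence_mass_ref=5.0))
        np.testing.assert_array_equal(a.state.X, b.state.X)
        assert a.params.mu == b.params.mu
        np.testing.assert_array_equal(a.region_posterior,
                                      b.region_posterior)

    def test_refit_from_converged_parameters_is_a_fixed_point(self,
                                                              full_dataset):
        cfg = HMRFConfig()
        first = fit(full_dataset, cfg=cfg)
        cfg2 = HMRFConfig(mu0=first.params.mu,
                          theta0=first.params.theta_region)
        second = fit(full_dataset, cfg=cfg2)
        assert abs(second.params.mu - first.params.mu) < 10 * cfg.tol
        assert np.array_equal(first.state.X, second.state.X)

    def test_pseudo_likelihood_trace_is_recorded(self, full_dataset):
        fitted = fit(full_dataset)
        assert len(fitted.trace) >= 1
        assert all(np.isfinite(t["loglik"]) for t in fitted.trace)


class TestEvidence:
    def test_site_evidence_sign_and_zero(self):
        labels = np.array([1] * 50 + [0] * 50)
        g = np.zeros((100, 3), dtype=bool)
        g[:5, 0] = True          # case-enriched
        g[50:55, 1] = True       # control-enriched
        g[48:52, 2] = True       # balanced
        m = site_evidence(g, labels)
        assert m[0] > 0 > m[1]
        assert abs(m[2]) < 0.1

    def test_error_posterior_rare_carrier_flagged_at_high_mu(self):
        labels = np.array([1] * 50 + [0] * 50)
        g = np.zeros((100, 2), dtype=bool)
        g[0, 0] = True           # singleton carrier
        g[:40, 1] = True
        g[50:90, 1] = True       # common carrier
        err = carrier_error_posterior(g, labels, mu=0.05)
        assert err[0, 0] > 0.5   # lone carrier likely erroneous
        assert err[0, 1] < 0.5   # carrier at a common site is trusted
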