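"""Simulation-layer tests: Wright sampler, risk model, generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from burdenmrf import (SimConfig, case_maf, generate_dataset,
                       generate_null_dataset, overlay_read_counts,
                       relative_risk, sample_wright_maf)
from burdenmrf.simdata import ReadOverlayConfig, WrightDistribution

PAPER = dict(sigma=12.0, beta_site=0.001, beta_repair=0.00033)


def wright_cdf_oracle(sigma, beta_i, beta_l):
    """Independent numeric CDF of Wright's density via quadrature.

    Endpoint power-law spikes are removed by the substitutions
    u = rho^beta_i (left half) and v = (1-rho)^beta_l (right half), after
    which the integrands are smooth and scipy.quad applies directly.
    """

    def left_mass(x):  # integral over (0, min(x, 0.5))
        hi = min(x, 0.5) ** beta_i

        def f(u):
            rho = u ** (1.0 / beta_i)
            return ((1 - rho) ** (beta_l - 1.0)
                    * np.exp(-sigma * rho) / beta_i)
        return integrate.quad(f, 0.0, hi, limit=200)[0]

    def right_mass(x):  # integral over (max(x, 0.5), 1)
        hi = (1.0 - max(x, 0.5)) ** beta_l

        def f(v):
            rho = 1.0 - v ** (1.0 / beta_l)
            return (rho ** (beta_i - 1.0)
                    * np.exp(-sigma * rho) / beta_l)
        return integrate.quad(f, 0.0, hi, limit=200)[0]

    z = left_mass(0.5) + right_mass(0.5)

    def cdf(x):
        x = float(x)
        if x <= 0:
            return 0.0
        if x >= 1:
            return 1.0
        if x <= 0.5:
            return left_mass(x) / z
        return 1.0 - right_mass(x) / z

    return cdf


class TestWrightSampler:
    def test_ks_against_numeric_cdf_at_reference_parameters(self):
        """Draws above the representable floor match the numerically
        integrated density (conditional KS, alpha=0.01, n=1e4 draws)."""
        cfg = SimConfig(**PAPER)
        rng = np.random.default_rng(123)
        x = sample_wright_maf(cfg, 10_000, rng)
        oracle = wright_cdf_oracle(12.0, 0.001, 0.00033)
        a = 1e-6
        fa = oracle(a)
        body = np.sort(x[x > a])
        assert body.size > 50

        def cond_cdf(v):
            return (np.vectorize(oracle)(v) - fa) / (1.0 - fa)

        ks = stats.kstest(body, cond_cdf)
        assert ks.pvalue > 0.01
        # mass below the cut matches the oracle (binomial check)
        k = int((x <= a).sum())
        lo, hi = stats.binom.interval(0.999, x.size, fa)
        assert lo <= k <= hi

    def test_beta_one_special_case_matches_truncated_exponential_mean(self):
        """With beta_i = beta_L = 1 the density is a truncated exponential
        on (0,1); the closed-form mean is 1/sigma - e^-sigma/(1-e^-sigma)."""
        cfg = SimConfig(sigma=12.0, beta_site=1 - 1e-12,
                        beta_repair=1 - 1e-12)
        # exact betas of 1.0 are valid too; use a fresh distribution object
        dist = WrightDistribution(12.0, 1.0, 1.0)
        rng = np.random.default_rng(5)
        x = dist.ppf(rng.random(100_000))
        mean_true = 1 / 12.0 - np.exp(-12.0) / (1 - np.exp(-12.0))
        assert abs(x.mean() - mean_true) < 4 * x.std() / np.sqrt(x.size)
        assert cfg.sigma == 12.0

    def test_empty_draw(self, rng):
        assert sample_wright_maf(SimConfig(**PAPER), 0, rng).size == 0

    def test_truncation_respects_upper_bound(self, rng):
        cfg = SimConfig(maf_upper=0.01, **PAPER)
        x = sample_wright_maf(cfg, 2000, rng)
        assert np.all(x <= 0.01) and np.all(x > 0)

    def test_invalid_betas_rejected(self):
        with pytest.raises(ValueError):
            WrightDistribution(12.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            SimConfig(beta_site=0.0)

    def test_reproducible_under_fixed_seed(self):
        cfg = SimConfig(**PAPER)
        a = sample_wright_maf(cfg, 100, np.random.default_rng(9))
        b = sample_wright_maf(cfg, 100, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestRiskModel:
    @pytest.mark.parametrize("delta,rho,expected", [
        (0.0, 0.01, 1.0),
        (0.001, 0.01, 1.0 + 0.001 / (0.999 * 0.01)),
        (0.0004, 0.005, 1.0 + 0.0004 / (0.9996 * 0.005)),
    ])
    def test_relative_risk_values(self, delta, rho, expected):
        assert relative_risk(delta, rho) == pytest.approx(expected,
                                                          rel=1e-12)

    def test_relative_risk_degenerate_rho(self):
        with pytest.raises(ValueError):
            relative_risk(0.001, 0.0)

    @pytest.mark.parametrize("rr,rho,expected", [
        (1.0, 0.01, 0.01),
        (2.0, 0.01, 0.02 / 1.01),
    ])
    def test_case_maf_values(self, rr, rho, expected):
        assert case_maf(rr, rho) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(delta=st.sampled_from([0.0]) | st.floats(1e-9, 0.5),
           rho=st.floats(1e-6, 0.99))
    def test_case_maf_of_relative_risk_properties(self, delta, rho):
        """theta in (0,1); fixes rho at delta=0; monotone in delta;
        RR >= 1 and decreasing in rho."""
        rr = relative_risk(delta, rho)
        theta = case_maf(rr, rho)
        assert rr >= 1.0
        assert 0.0 < theta < 1.0
        if delta == 0.0:
            assert theta == pytest.approx(rho)
        else:
            assert theta >= rho  # equality only at float resolution
            assert relative_risk(delta, min(rho * 2, 0.995)) < rr
            bigger = case_maf(relative_risk(min(delta * 2, 0.9), rho), rho)
            assert bigger >= theta

    def test_case_maf_below_one_for_large_rr(self):
        assert case_maf(1e9, 0.01) < 1.0


class TestGenerateDataset:
    def test_reference_shape_and_fixed_causal_count(self, full_dataset):
        ds = full_dataset
        assert ds.genotypes.values.shape == (2000, 100)
        assert int(ds.causal_truth.sum()) == 50
        assert np.all(ds.case_mafs[ds.causal_truth == 1]
                      >= ds.control_mafs[ds.causal_truth == 1])
        assert np.all((ds.control_mafs > 0) & (ds.control_mafs < 1))
        # polymorphism conditioning: every site is an observed variant
        assert np.all(ds.genotypes.carriers().sum(axis=0) >= 1)

    def test_null_par_gives_balanced_arms(self):
        cfg = SimConfig(group_par=0.0, seed=3)
        ds = generate_dataset(cfg, np.random.default_rng(3))
        g = ds.genotypes.carriers()
        a = g[ds.labels == 1].sum()
        b = g[ds.labels == 0].sum()
        # equal in expectation; totals are in the thousands
        assert abs(a - b) < 4 * np.sqrt(a + b)

    def test_causal_site_carrier_frequency_matches_risk_model(self):
        """C=1, M=2: case carrier frequency at the causal site is within
        3 Monte-Carlo SEs of 1-(1-theta)^2 with theta from the RR model."""
        cfg = SimConfig(n_cases=20000, n_controls=20000, n_sites=2,
                        n_causal=1, group_par=0.05,
                        require_polymorphic=False, seed=21, **PAPER)
        ds = generate_dataset(cfg, np.random.default_rng(21))
        s = int(np.nonzero(ds.causal_truth)[0][0])
        rho = ds.control_mafs[s]
        theta = case_maf(relative_risk(cfg.delta, rho), rho)
        p = 1 - (1 - theta) ** 2
        obs = ds.genotypes.carriers()[ds.labels == 1, s].mean()
        se = np.sqrt(p * (1 - p) / 20000)
        assert abs(obs - p) <= 3 * se + 1e-9

    def test_bit_reproducible(self):
        cfg = SimConfig(n_cases=100, n_controls=100, n_sites=10,
                        n_causal=3, seed=5)
        a = generate_dataset(cfg, np.random.default_rng(5))
        b = generate_dataset(cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a.genotypes.values,
                                      b.genotypes.values)
        np.testing.assert_array_equal(a.control_mafs, b.control_mafs)

    def test_diploid_coding_collapses_to_carrier(self):
        cfg = SimConfig(n_cases=200, n_controls=200, n_sites=10,
                        n_causal=2, coding="diploid", seed=8)
        ds = generate_dataset(cfg, np.random.default_rng(8))
        assert ds.genotypes.values.max() <= 2
        assert np.array_equal(ds.genotypes.carriers(),
                              ds.genotypes.values > 0)


class TestNullDataset:
    def test_expected_total_carriers(self):
        ds = generate_null_dataset(1000, 100, 0.005,
                                   np.random.default_rng(2))
        total = int(ds.genotypes.values.sum())
        assert abs(total - 500) < 4 * np.sqrt(500)
        assert int(ds.causal_truth.sum()) == 0

    def test_zero_mutation_probability(self):
        ds = generate_null_dataset(50, 20, 0.0, np.random.default_rng(1))
        assert ds.genotypes.values.sum() == 0

    def test_label_balance(self):
        ds = generate_null_dataset(10_000, 2, 0.005,
                                   np.random.default_rng(4))
        frac = ds.labels.mean()
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(10_000)


class TestReadOverlay:
    def test_carrier_support_mean(self, small_dataset, rng):
        ds = overlay_read_counts(small_dataset,
                                 ReadOverlayConfig(depth_mean=100.0), rng)
        rc = ds.read_counts
        carr = ds.genotypes.carriers()
        vaf = rc.tumor_support[carr] / rc.tumor_depth[carr]
        assert abs(vaf.mean() - 0.5) < 0.02
        assert np.all(rc.tumor_support <= rc.tumor_depth)
        assert rc.tumor_depth.min() >= 1

    def test_zero_error_rate_gives_zero_noncarrier_support(self,
                                                           small_dataset,
                                                           rng):
        ds = overlay_read_counts(small_dataset,
                                 ReadOverlayConfig(error_rate=0.0), rng)
        noncarr = ~ds.genotypes.carriers()
        assert ds.read_counts.tumor_support[noncarr].sum() == 0

    def test_two_subclone_vafs_recovered(self, small_dataset, rng):
        overlay = ReadOverlayConfig(
            depth_mean=200.0, error_rate=0.0,
            somatic_sites=(0, 1), somatic_vaf={0: 0.4, 1: 0.1})
        ds = overlay_read_counts(small_dataset, overlay, rng)
        carr = ds.genotypes.carriers()
        for s, target in ((0, 0.4), (1, 0.1)):
            idx = carr[:, s]
            if idx.sum() == 0:
                continue
            vaf = (ds.read_counts.tumor_support[idx, s]
                   / ds.read_counts.tumor_depth[idx, s])
            assert abs(vaf.mean() - target) < 0.05
            normal = ds.read_counts.normal_support[idx, s]
            assert normal.sum() == 0  # somatic: absent from normal tissue
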