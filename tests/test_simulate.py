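"""Simulator: covariate laws, intercept rescaling, counts, event inversion."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from microjoint import (SimulationConfig, rescale_intercept,
                        simulate_covariates, simulate_counts,
                        simulate_event_times, simulate_joint_dataset)
from microjoint.hazard import HazardParams, QuadratureRule, hazard_at
from microjoint.simulate import _eta_no_offset


class TestCovariates:
    def test_binary_law_means(self):
        cfg = SimulationConfig(n_subjects=1000, k_samples=2)
        cov = simulate_covariates(cfg, rng=1)
        assert abs(cov.X1.mean() - 0.5) < 0.05
        assert abs(cov.W1.mean() - 0.5) < 0.05
        assert abs(cov.W2.mean() - 0.3) < 0.05

    def test_library_size_law(self):
        cfg = SimulationConfig(n_subjects=1000, k_samples=10)
        cov = simulate_covariates(cfg, rng=2)
        assert abs(cov.C.mean() - 10_000) / 10_000 < 0.01
        assert np.all(cov.C >= 1)
        assert cov.C.dtype == np.int64

    def test_times_within_sampling_window(self):
        cfg = SimulationConfig(n_subjects=200, k_samples=5)
        cov = simulate_covariates(cfg, rng=3)
        assert cov.t.min() >= 0 and cov.t.max() <= cfg.time_upper

    def test_zero_variances_give_zero_random_effects(self):
        cfg = SimulationConfig(n_subjects=50, k_samples=3, d11=0.0, d22=0.0)
        cov = simulate_covariates(cfg, rng=4)
        assert np.all(cov.b == 0)

    def test_random_effect_covariance_literal_parameterization(self):
        cfg = SimulationConfig()
        # off-diagonal is rho * d11 * d22 (a product of variances)
        assert np.isclose(cfg.D[0, 1], 0.5 * 0.003 * 0.001)
        assert np.isclose(cfg.D[0, 0], 0.003)
        assert np.isclose(cfg.D[1, 1], 0.001)


class TestRescaleIntercept:
    def test_by_construction(self):
        beta0 = rescale_intercept([0.0, 1.0, 2.0], eps=0.1)
        assert np.isclose(beta0, -2.1)
        assert np.isclose(np.exp(np.max([0, 1, 2]) + beta0), np.exp(-0.1))

    def test_all_equal_eta(self):
        beta0 = rescale_intercept([0.7, 0.7], eps=0.25)
        assert np.allclose(np.exp(np.array([0.7, 0.7]) + beta0),
                           np.exp(-0.25))

    def test_shift_invariance(self):
        eta = np.array([-1.0, 0.3, 2.2])
        b0 = rescale_intercept(eta, 0.1)
        b0c = rescale_intercept(eta + 5.0, 0.1)
        assert np.isclose(b0c, b0 - 5.0)
        assert np.allclose(np.exp(eta + b0), np.exp(eta + 5.0 + b0c))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rescale_intercept([], 0.1)


class TestCounts:
    def test_mean_relative_abundance_matches_target(self):
        # one design row replicated: empirical mean of y/C ~ p within 2%
        cfg = SimulationConfig(n_subjects=1, k_samples=10_000, d11=0, d22=0)
        cov = simulate_covariates(cfg, rng=5)
        cov.t[:] = 4.0
        beta0 = -6.0
        series, _ = simulate_counts(cfg, cov, beta0, rng=6)
        p = np.exp(beta0 + cfg.beta1 * cov.X1[0] + (cfg.beta2
                   + cfg.beta3 * cov.X1[0]) * 4.0)
        emp = np.mean(series.y / series.C)
        assert abs(emp - p) / p < 0.02

    def test_poisson_limit_variance(self):
        cfg = SimulationConfig(n_subjects=1, k_samples=20_000, d11=0, d22=0,
                               theta=1e8, library_sd=0.0)
        cov = simulate_covariates(cfg, rng=7)
        cov.t[:] = 2.0
        series, _ = simulate_counts(cfg, cov, -5.0, rng=8)
        y = series.y.astype(float)
        assert abs(y.var() / y.mean() - 1.0) < 0.05

    def test_large_margin_bounds_abundance(self):
        cfg = SimulationConfig(n_subjects=50, k_samples=4, eps=5.0)
        cov = simulate_covariates(cfg, rng=9)
        beta0 = rescale_intercept(_eta_no_offset(cfg, cov, 0.0), cfg.eps)
        series, _ = simulate_counts(cfg, cov, beta0, rng=10)
        p = np.exp(_eta_no_offset(cfg, cov, beta0))
        assert p.max() <= np.exp(-5.0) + 1e-12


class TestEventTimes:
    def test_alpha_zero_times_are_exponential(self):
        cfg = SimulationConfig(n_subjects=5000, k_samples=1, alpha=0.0,
                               gamma1=0.0, gamma2=0.0, t_max=200.0)
        cov = simulate_covariates(cfg, rng=11)
        records, latent, censored = simulate_event_times(cfg, cov, -3.0,
                                                         rng=12)
        times = latent[~censored]
        assert len(times) >= 4990
        ks = stats.kstest(times, "expon", args=(0, 1 / cfg.lam))
        assert ks.pvalue > 0.01

    def test_root_finder_residual(self):
        # |H(T) + log U| < 1e-8 at the returned root, over random draws
        cfg = SimulationConfig(n_subjects=100, k_samples=3)
        cov = simulate_covariates(cfg, rng=13)
        beta0 = rescale_intercept(_eta_no_offset(cfg, cov, 0.0), cfg.eps)
        rng = np.random.default_rng(14)
        U = rng.uniform(size=cfg.n_subjects)

        rule = QuadratureRule.gauss_legendre(cfg.quad_order)
        records, latent, censored = simulate_event_times(
            cfg, cov, beta0, rng=np.random.default_rng(14), rule=rule)
        a1 = beta0 + cfg.beta1 * cov.X1 + cov.b[:, 0]
        a2 = cfg.beta2 + cfg.beta3 * cov.X1 + cov.b[:, 1]
        checked = 0
        for i in np.flatnonzero(~censored):
            T = latent[i]
            u = T * rule.nodes
            H = (cfg.lam * np.exp(cfg.gamma1 * cov.W1[i]
                                  + cfg.gamma2 * cov.W2[i]) * T
                 * float(rule.weights @ np.exp(
                     cfg.alpha * cfg.phi * np.exp(a1[i] + a2[i] * u))))
            assert abs(H + np.log(U[i])) < 1e-8
            checked += 1
        assert checked >= 50

    def test_observed_times_capped_at_tmax(self):
        cfg = SimulationConfig(n_subjects=300, k_samples=5)
        ds, truth = simulate_joint_dataset(cfg, seed=15)
        ev = ds.events_frame()
        assert ev["event_time"].max() <= cfg.t_max
        assert set(ev.loc[ev["event_time"] == cfg.t_max, "status"]) <= {0}

    def test_larger_alpha_accelerates_events(self):
        cfg0 = SimulationConfig(n_subjects=400, k_samples=3, alpha=0.0)
        cfg1 = dataclasses.replace(cfg0, alpha=2.0)
        cov = simulate_covariates(cfg0, rng=16)
        beta0 = rescale_intercept(_eta_no_offset(cfg0, cov, 0.0), cfg0.eps)
        _, lat0, c0 = simulate_event_times(cfg0, cov, beta0, rng=17)
        _, lat1, c1 = simulate_event_times(cfg1, cov, beta0, rng=17)
        med0 = np.median(np.where(c0, cfg0.t_max, lat0))
        med1 = np.median(np.where(c1, cfg1.t_max, lat1))
        assert med1 < med0

    def test_censoring_nonincreasing_in_lambda(self):
        fracs = []
        for lam in (0.02, 0.1, 0.5):
            cfg = SimulationConfig(n_subjects=400, k_samples=3, lam=lam)
            cov = simulate_covariates(cfg, rng=18)
            beta0 = rescale_intercept(_eta_no_offset(cfg, cov, 0.0), cfg.eps)
            _, _, censored = simulate_event_times(cfg, cov, beta0, rng=19)
            fracs.append(censored.mean())
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_simulator_hazard_matches_hazard_module(self):
        # single source of the hazard formula
        cfg = SimulationConfig(n_subjects=5, k_samples=3)
        cov = simulate_covariates(cfg, rng=20)
        beta0 = rescale_intercept(_eta_no_offset(cfg, cov, 0.0), cfg.eps)
        params = cfg.hazard_params()
        i = 2
        a1 = beta0 + cfg.beta1 * cov.X1[i] + cov.b[i, 0]
        a2 = cfg.beta2 + cfg.beta3 * cov.X1[i] + cov.b[i, 1]
        rel = lambda t: np.exp(a1 + a2 * np.asarray(t))
        w = [cov.W1[i], cov.W2[i]]
        for t in (0.5, 3.0, 7.5):
            h_module = hazard_at(t, w, rel, params)
            h_sim = (cfg.lam * np.exp(cfg.gamma1 * cov.W1[i]
                                      + cfg.gamma2 * cov.W2[i]
                                      + cfg.alpha * cfg.phi * rel(t)))
            assert np.isclose(h_module, h_sim, rtol=1e-12)


class TestEndToEnd:
    def test_reproducible_from_config_and_seed(self):
        cfg = SimulationConfig(n_subjects=60, k_samples=4)
        ds1, tr1 = simulate_joint_dataset(cfg, seed=21)
        ds2, tr2 = simulate_joint_dataset(cfg, seed=21)
        import pandas as pd
        pd.testing.assert_frame_equal(ds1.series.frame, ds2.series.frame)
        assert tr1.beta0 == tr2.beta0
        assert np.array_equal(tr1.latent_event_times, tr2.latent_event_times)

    def test_every_kept_subject_has_rows_and_drops_reported(self):
        cfg = SimulationConfig(n_subjects=200, k_samples=4)
        ds, truth = simulate_joint_dataset(cfg, seed=22)
        counts = ds.series.frame.groupby("subject_id").size()
        assert (counts >= 1).all()
        assert len(truth.dropped_subjects) + ds.n_subjects == cfg.n_subjects

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=0)
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(t_max=-1.0)
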