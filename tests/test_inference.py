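"""Joint posterior, HDI, sampler behaviour and hazard-ratio summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microjoint import (EventRecord, JointParams, PriorSpec,
                        SimulationConfig, assemble_joint_dataset,
                        event_loglik, fit_joint, hdi, joint_log_posterior,
                        nb_log_pmf, simulate_joint_dataset,
                        summarize_hazard_ratios)
from microjoint.hazard import HazardParams
from microjoint.io_data import TaxonSeries


def _one_subject_dataset():
    frame = pd.DataFrame({"sample_id": ["a"], "subject_id": ["P1"],
                          "time": [1.0], "y": [7], "C": [1000],
                          "X1": [1.0]})
    series = TaxonSeries(frame=frame, formula="y ~ X1 + Time + (Time|ID)")
    events = [EventRecord("P1", 2.0, 0, {"W1": 1.0})]
    return assemble_joint_dataset(series, events)


class TestJointLogPosterior:
    def test_term_by_term_oracle(self):
        """One subject, one observation: the joint log posterior equals the
        hand-computed sum of NB + event + random-effect + prior terms."""
        data = _one_subject_dataset()
        params = JointParams(beta=[-4.0, 0.5, 0.1], b=[[0.05, -0.02]],
                             tau=[0.1, 0.05], theta=2.0, lam=0.1,
                             gamma=[0.3], alpha=0.4, rho=0.2, phi=10.0)
        total = joint_log_posterior(data, params)

        # longitudinal term
        eta = (-4.0 + 0.5 * 1 + 0.1 * 1.0 + 0.05 - 0.02 * 1.0
               + np.log(1000.0))
        ll_long = nb_log_pmf(7, np.exp(eta), 2.0)
        # event term via the hazard module (censored at T=2)
        rel = lambda t: np.exp(-4.0 + 0.5 + 0.1 * np.asarray(t)
                               + 0.05 - 0.02 * np.asarray(t))
        hp = HazardParams(rate=0.1, gamma=np.array([0.3]), alpha=0.4,
                          phi=10.0)
        ll_event = event_loglik(2.0, 0, [1.0], rel, hp)
        # random-effect prior
        D = params.D
        ll_b = stats.multivariate_normal.logpdf([0.05, -0.02], cov=D)
        # global priors (same unnormalized convention as the model)
        pr = PriorSpec()
        lp = (-0.5 * np.sum(np.array([-4.0, 0.5, 0.1]) ** 2) / 25.0
              - 0.5 * 0.3 ** 2 / 25.0 - 0.5 * 0.4 ** 2 / 25.0
              - 0.5 * np.log(0.1) ** 2 / 25.0
              + (-1.0 / 2.0 - np.log(2.0))
              + np.sum(-0.5 * np.array([0.1, 0.05]) ** 2
                       + np.log([0.1, 0.05]))
              + 2.0 * np.log(1 - 0.2 ** 2))
        assert np.isclose(total, ll_long + ll_event + ll_b + lp, atol=1e-8)

    def test_duplicating_subjects_doubles_data_loglik(self):
        cfg = SimulationConfig(n_subjects=20, k_samples=3)
        ds, _ = simulate_joint_dataset(cfg, seed=1)
        n = ds.n_subjects
        params = JointParams(beta=[-5.0, 0.5, 0.2, 0.1],
                             b=np.zeros((n, 2)), tau=[0.1, 0.05],
                             theta=2.0, lam=0.1, gamma=[0.1, -0.1],
                             alpha=0.2)
        base = joint_log_posterior(ds, params)

        # doubled dataset: every subject cloned under a new id
        f = ds.series.frame.copy()
        f2 = f.copy()
        f2["subject_id"] = f2["subject_id"] + "_dup"
        f2["sample_id"] = f2["sample_id"] + "_dup"
        series = TaxonSeries(frame=pd.concat([f, f2], ignore_index=True),
                             formula=ds.series.formula)
        events = ds.events + [
            EventRecord(e.subject_id + "_dup", e.event_time, e.status,
                        dict(e.covariates)) for e in ds.events]
        ds2 = assemble_joint_dataset(series, events)
        params2 = JointParams(beta=params.beta, b=np.zeros((2 * n, 2)),
                              tau=params.tau, theta=2.0, lam=0.1,
                              gamma=params.gamma, alpha=0.2)
        doubled = joint_log_posterior(ds2, params2)
        # (data + b-prior) part doubles; the global prior stays fixed
        from microjoint._model import JointModel, ModelData
        model = JointModel(ModelData.from_dataset(ds))
        parts = {"beta": np.asarray(params.beta), "gamma":
                 np.asarray(params.gamma), "alpha": 0.2,
                 "log_rate": np.log(0.1), "rate": 0.1, "log_shape": 0.0,
                 "shape": 1.0, "log_disp": np.log(2.0), "disp": 2.0,
                 "tau": np.array([0.1, 0.05]),
                 "log_tau": np.log([0.1, 0.05]), "rho": 0.0, "z_rho": 0.0}
        gp = model.prior_logp(parts)
        assert np.isclose(doubled - gp, 2 * (base - gp), rtol=1e-10)

    def test_nonfinite_flagged(self):
        data = _one_subject_dataset()
        params = JointParams(beta=[np.nan, 0.0, 0.0], b=[[0.0, 0.0]],
                             tau=[0.1, 0.1], theta=2.0, lam=0.1,
                             gamma=[0.0], alpha=0.5)
        with pytest.raises(FloatingPointError, match="beta"):
            joint_log_posterior(data, params)


class TestHdi:
    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 1.7), 0.9)
        assert lo == hi == 1.7

    def test_normal_draws_match_quantiles(self):
        x = np.random.default_rng(0).standard_normal(10 ** 6)
        lo, hi = hdi(x, 0.95)
        assert abs(lo + 1.96) < 0.02 and abs(hi - 1.96) < 0.02

    def test_shortest_window_bruteforce_on_skewed_draws(self):
        rng = np.random.default_rng(1)
        for prob in (0.5, 0.8, 0.95):
            x = np.sort(rng.exponential(size=400))
            k = int(np.ceil(prob * len(x)))
            widths = [x[j + k - 1] - x[j] for j in range(len(x) - k + 1)]
            j = int(np.argmin(widths))
            assert hdi(x, prob) == (x[j], x[j + k - 1])

    def test_exponential_hdi_anchored_at_zero(self):
        x = np.random.default_rng(2).exponential(size=20_000)
        lo, hi = hdi(x, 0.5)
        assert lo < np.quantile(x, 0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hdi(np.arange(10), 0.9)
        with pytest.raises(ValueError):
            hdi(np.arange(1000), 1.5)


class TestFitJoint:
    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(n_subjects=40, k_samples=3)
        ds, _ = simulate_joint_dataset(cfg, seed=5)
        kw = dict(chains=2, warmup=150, draws=60, seed=9, rhat_warn=np.inf)
        p1 = fit_joint(ds, **kw)
        p2 = fit_joint(ds, **kw)
        for name in p1.names:
            assert np.array_equal(p1.draws[name], p2.draws[name])

    def test_requires_events_and_chains(self):
        cfg = SimulationConfig(n_subjects=30, k_samples=3)
        ds, _ = simulate_joint_dataset(cfg, seed=6)
        with pytest.raises(ValueError):
            fit_joint(ds, chains=1)

    def test_parameter_recovery_and_hdi_coverage(self, fitted_sim):
        """Generating values fall inside the 95% HDIs of a converged fit."""
        cfg, dataset, truth, post = fitted_sim
        for name, true_val in [("alpha", cfg.alpha), ("lambda", cfg.lam),
                               ("theta", cfg.theta),
                               ("beta[X1]", cfg.beta1),
                               ("beta[Time]", cfg.beta2),
                               ("beta[(Intercept)]", truth.beta0),
                               ("gamma[W1]", cfg.gamma1),
                               ("gamma[W2]", cfg.gamma2)]:
            lo, hi = post.hdi(name, 0.95)
            assert lo <= true_val <= hi, (name, true_val, lo, hi)

    def test_null_alpha_recovery(self):
        cfg = SimulationConfig(n_subjects=120, k_samples=4, alpha=0.0)
        ds, _ = simulate_joint_dataset(cfg, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_joint(ds, chains=2, warmup=500, draws=250, seed=2)
        lo, hi = post.hdi("alpha", 0.95)
        assert lo <= 0.0 <= hi

    def test_diagnostics_reported(self, fitted_sim):
        *_, post = fitted_sim
        assert set(post.diagnostics) >= {"rhat", "ess", "chains"}
        assert all(np.isfinite(v) for v in post.diagnostics["rhat"].values())

    def test_posterior_write(self, fitted_sim, tmp_path):
        *_, post = fitted_sim
        post.write(tmp_path)
        draws = pd.read_csv(tmp_path / "draws.csv")
        assert len(draws) == post.n_chains * post.n_draws
        assert "alpha" in draws.columns
        import json
        summ = json.loads((tmp_path / "summary.json").read_text())
        assert summ["phi"] == post.phi


class TestHazardRatios:
    def _post_with(self, alpha_draws, gamma_draws):
        from microjoint.inference import Posterior
        return Posterior(
            draws={"gamma[W1]": gamma_draws[None, :],
                   "alpha": alpha_draws[None, :],
                   "lambda": np.full((1, len(alpha_draws)), 0.1)},
            b_draws=None, subjects=[], phi=10.0, link="nb",
            baseline="exponential", priors=PriorSpec())

    def test_point_mass_draws(self):
        n = 200
        tab = self._post_with(np.full(n, np.log(1.5)), np.zeros(n))
        tab = summarize_hazard_ratios(tab)
        alpha_row = tab[tab.parameter == "alpha"].iloc[0]
        gamma_row = tab[tab.parameter == "gamma[W1]"].iloc[0]
        assert np.isclose(alpha_row.hazard_ratio, 1.5)
        assert np.isclose(gamma_row.hazard_ratio, 1.0)
        assert "10" in alpha_row.unit

    def test_monotone_transform_of_hdi(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(0.2, 0.3, size=2000)
        post = self._post_with(draws, rng.normal(size=2000))
        tab = summarize_hazard_ratios(post, probs=(0.95,))
        row = tab[tab.parameter == "alpha"].iloc[0]
        lo, hi = hdi(draws, 0.95)
        assert np.isclose(row.hr_hdi95_lo, np.exp(lo))
        assert np.isclose(row.hr_hdi95_hi, np.exp(hi))
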