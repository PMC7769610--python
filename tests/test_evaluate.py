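"""ROC/AUC, Cox and Gaussian comparators, recovery harness."""

import warnings

import numpy as np
import pandas as pd
import pytest

from microjoint import (EventRecord, SimulationConfig, fit_cox_comparator,
                        fit_gaussian_joint_comparator, roc_auc,
                        recovery_grid, simulate_joint_dataset)


def auc_bruteforce(scores, outcomes):
    """Exhaustive pairwise concordance (ties counted 1/2)."""
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, int)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_random_scores_near_half(self, rng):
        outcomes = rng.integers(0, 2, size=4000)
        scores = rng.permutation(outcomes.astype(float))
        r = roc_auc(scores, outcomes)
        assert abs(r.auc - 0.5) < 0.03

    def test_six_point_toy_equals_concordance(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9]
        outcomes = [0, 0, 1, 1, 0, 1]
        assert np.isclose(roc_auc(scores, outcomes).auc,
                          auc_bruteforce(scores, outcomes))

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 50))
            scores = rng.integers(0, 5, size=n) / 4.0   # heavy ties
            outcomes = rng.integers(0, 2, size=n)
            if len(np.unique(outcomes)) < 2:
                continue
            assert np.isclose(roc_auc(scores, outcomes).auc,
                              auc_bruteforce(scores, outcomes))

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(size=200)
        outcomes = rng.integers(0, 2, size=200)
        a1 = roc_auc(scores, outcomes).auc
        a2 = roc_auc(np.exp(3 * scores) + 7, outcomes).auc
        assert np.isclose(a1, a2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCoxComparator:
    def _events(self, rng, n, hr_w1=1.0):
        # exponential times with hazard 0.1 * hr_w1^W1
        W1 = rng.integers(0, 2, size=n)
        T = rng.exponential(1.0 / (0.1 * hr_w1 ** W1))
        cens = np.minimum(T, 30.0)
        return [EventRecord(f"P{i}", float(max(cens[i], 1e-3)),
                            int(T[i] <= 30.0), {"W1": float(W1[i])})
                for i in range(n)]

    def test_null_coefficients_near_zero(self, rng):
        cox = fit_cox_comparator(self._events(rng, 600, hr_w1=1.0))
        se = cox._fitter.standard_errors_["W1"]
        assert abs(cox.coefficients["W1"]) < 2 * se

    def test_log_hazard_ratio_consistency(self, rng):
        cox = fit_cox_comparator(self._events(rng, 2000, hr_w1=2.0))
        assert abs(cox.coefficients["W1"] - np.log(2.0)) < 0.15

    def test_survival_prediction_starts_at_one(self, rng):
        cox = fit_cox_comparator(self._events(rng, 200))
        S0 = cox.predict_event_free(pd.DataFrame({"W1": [0.0, 1.0]}), 1e-9)
        assert np.allclose(S0, 1.0, atol=1e-6)

    def test_requires_events(self):
        recs = [EventRecord("P1", 1.0, 0, {"W1": 0.0}),
                EventRecord("P2", 2.0, 0, {"W1": 1.0})]
        with pytest.raises(ValueError):
            fit_cox_comparator(recs)


class TestGaussianComparator:
    def test_biases_on_nb_data(self, fitted_sim):
        """On NB-generated counts the Gaussian joint model's longitudinal
        intercept is biased low and its baseline hazard is overestimated,
        while the NB joint model tracks the truth."""
        cfg, dataset, truth, post_nb = fitted_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post_g = fit_gaussian_joint_comparator(
                dataset, chains=2, warmup=600, draws=300, seed=4)
        assert post_g.median("beta[(Intercept)]") < truth.beta0
        assert post_g.median("lambda") > post_nb.median("lambda")
        assert "sigma" in post_g.names

    def test_recovers_own_generating_process(self, rng):
        """Sanity: on truly Gaussian log-abundance data the comparator
        recovers its own parameters."""
        import pandas as pd
        from microjoint.io_data import (EventRecord, TaxonSeries,
                                        assemble_joint_dataset)
        n_subj, k = 150, 5
        beta = np.array([-4.0, 0.6, 0.25])   # intercept, X1, time
        sigma = 0.4
        rows, events = [], []
        for i in range(n_subj):
            X1 = float(rng.integers(0, 2))
            b0 = rng.normal(0, 0.1)
            times = np.sort(rng.uniform(0, 8, size=k))
            C = np.maximum(1, np.rint(rng.normal(10000, 1000, k))).astype(int)
            m = beta[0] + beta[1] * X1 + beta[2] * times + b0
            v = rng.normal(m, sigma)
            y = np.clip(np.rint(np.exp(v) * C - 0.5), 0, C).astype(int)
            T = min(float(rng.exponential(1 / 0.1)), 10.0)
            delta = int(T < 10.0)
            keep = times <= T
            if not keep.any():
                continue
            for j in np.flatnonzero(keep):
                rows.append({"sample_id": f"P{i}_{j}", "subject_id": f"P{i}",
                             "time": times[j], "y": y[j], "C": C[j],
                             "X1": X1})
            events.append(EventRecord(f"P{i}", T, delta,
                                      {"W1": float(rng.integers(0, 2))}))
        series = TaxonSeries(frame=pd.DataFrame(rows),
                             formula="y ~ X1 + Time + (1|ID)")
        ds = assemble_joint_dataset(series, events)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = fit_gaussian_joint_comparator(ds, chains=2, warmup=500,
                                                 draws=250, seed=5)
        lo, hi = post.hdi("beta[X1]", 0.95)
        assert lo <= beta[1] <= hi
        assert abs(post.median("sigma") - sigma) < 0.1
        lo, hi = post.hdi("alpha", 0.95)
        assert lo <= 0.0 <= hi


class TestRecoveryGrid:
    def test_smoke_run_and_mse_shape(self):
        cfg = SimulationConfig(n_subjects=50, k_samples=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = recovery_grid(N_set=(50,), K_set=(3, 5), replicates=2,
                                config_template=cfg, seed=11,
                                fit_kwargs=dict(chains=2, warmup=250,
                                                draws=120,
                                                rhat_warn=np.inf))
        assert set(res.table.columns) >= {"N", "K", "mse", "n_failed"}
        assert len(res.table) == 2
        assert (res.table["mse"].dropna() >= 0).all()

    def test_replicates_validated(self):
        with pytest.raises(ValueError):
            recovery_grid(replicates=1)
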