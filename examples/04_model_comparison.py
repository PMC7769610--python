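"""Compare the NB joint model against Cox and Gaussian-joint alternatives.

Simulates one study, fits all three models and scores their event-free
predictions (1 - S_hat at t_max) by ROC AUC among subjects still at risk
at each landmark.  The covariate-only Cox model cannot see the
abundance-driven late events; at the last landmark the survivors'
covariate risk anti-correlates with their abundance risk, which can push
the Cox AUC below 0.5.
"""

import warnings

from microjoint import (SimulationConfig, event_free_scores,
                        fit_cox_comparator, fit_gaussian_joint_comparator,
                        fit_joint, roc_auc, simulate_joint_dataset)

config = SimulationConfig(n_subjects=200, k_samples=8)
dataset, truth = simulate_joint_dataset(config, seed=11)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    fits = {
        "nb_joint": fit_joint(dataset, chains=2, warmup=700, draws=350,
                              seed=1),
        "gaussian_joint": fit_gaussian_joint_comparator(
            dataset, chains=2, warmup=700, draws=350, seed=2),
        "cox": fit_cox_comparator(dataset.events),
    }

print(f"alpha = {config.alpha}, N = {dataset.n_subjects}")
print(f"{'landmark':>8} {'nb_joint':>9} {'gaussian':>9} {'cox':>7}")
for landmark in (1.0, 4.0, 8.0):
    row = []
    for name in ("nb_joint", "gaussian_joint", "cox"):
        sc = event_free_scores(fits[name], dataset, landmark, t_max=10.0,
                               seed=3, max_draws=120, n_steps=150)
        row.append(roc_auc(sc["score"], sc["outcome"]).auc)
    print(f"{landmark:>8.0f} {row[0]:>9.3f} {row[1]:>9.3f} {row[2]:>7.3f}")
# The joint models keep discriminating as the landmark moves late; the
# Cox model degrades because its covariate-only risk says nothing about
# the rising taxon abundance that drives the remaining events.
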