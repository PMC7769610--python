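"""Comparator models, ROC/AUC evaluation and parameter-recovery harness.

The NB joint model is compared against the two analytic alternatives a
practitioner would otherwise reach for:

* a Cox proportional-hazards model on the baseline covariates only
  (ignores the microbiome entirely), fitted by partial likelihood with a
  Breslow baseline via lifelines;
* the classic Gaussian joint model, with the longitudinal submodel on
  log-transformed relative abundances log((y + pseudocount) / C) and the
  fitted value entering the hazard linearly.

Predictive performance is scored by the AUC of 1 - S_hat(t_max | data <= t)
against the event-by-t_max outcome among subjects still at risk at the
landmark t.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import Posterior, fit_joint
from .io_data import JointDataset
from .predict import predict_event_free
from .simulate import SimulationConfig, simulate_joint_dataset

__all__ = [
    "ROCResult", "RecoveryGridResult", "CoxComparator",
    "fit_cox_comparator", "fit_gaussian_joint_comparator", "roc_auc",
    "event_free_scores", "compare_models", "plot_auc_table",
    "recovery_grid",
]

logger = logging.getLogger("microjoint")


@dataclass
class ROCResult:
    """ROC curve and AUC of event-free-probability scores."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    landmark: float | None = None
    generator_alpha: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class RecoveryGridResult:
    """Per-(N, K) recovery of the abundance effect size alpha."""

    table: pd.DataFrame            # columns: N, K, replicates, mse, n_failed
    errors: pd.DataFrame = field(repr=False, default=None)  # per-replicate


def roc_auc(scores, outcomes, landmark: float | None = None,
            generator_alpha: float | None = None) -> ROCResult:
    """ROC curve and trapezoid AUC (equals the Mann-Whitney statistic).

    ``scores`` are risk scores (here 1 - S_hat(t_max | data <= t));
    ``outcomes`` the binary event-by-t_max indicators.  Both classes must
    be present.
    """
    from sklearn.metrics import roc_curve, auc as _auc
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes).astype(int)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both outcome classes must be present to compute a ROC")
    fpr, tpr, thr = roc_curve(outcomes, scores)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=float(_auc(fpr, tpr)), landmark=landmark,
                     generator_alpha=generator_alpha)


class CoxComparator:
    """Cox proportional-hazards fit on the baseline event covariates only."""

    def __init__(self, fitter, w_names: list):
        self._fitter = fitter
        self.w_names = w_names

    @property
    def coefficients(self) -> pd.Series:
        return self._fitter.params_

    def predict_event_free(self, covariates: pd.DataFrame, t: float,
                           landmark: float = 0.0) -> np.ndarray:
        """S(t | w, T > landmark) from the Breslow baseline.

        The baseline survival is a right-continuous step function equal
        to 1 before the first observed event time.
        """
        sf = self._fitter.predict_survival_function(covariates)
        grid = sf.index.to_numpy(dtype=float)

        def at(time):
            j = np.searchsorted(grid, time + 1e-12) - 1
            if j < 0:
                return np.ones(sf.shape[1])
            return sf.iloc[j].to_numpy()

        s_t = at(t)
        if landmark > 0:
            s_l = at(landmark)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(s_l > 0, np.clip(s_t / s_l, 0.0, 1.0), 0.0)
        return s_t


def fit_cox_comparator(events) -> CoxComparator:
    """Fit the covariate-only Cox model (partial likelihood, Breslow)."""
    from lifelines import CoxPHFitter
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        rows = [{"subject_id": e.subject_id, "event_time": e.event_time,
                 "status": e.status, **e.covariates} for e in events]
        df = pd.DataFrame(rows)
    if df["status"].sum() < 2:
        raise ValueError("need at least 2 observed events for the Cox fit")
    w_names = [c for c in df.columns
               if c not in ("subject_id", "event_time", "status")]
    cph = CoxPHFitter()
    cph.fit(df[["event_time", "status"] + w_names],
            duration_col="event_time", event_col="status")
    return CoxComparator(cph, w_names)


def fit_gaussian_joint_comparator(dataset: JointDataset,
                                  pseudocount: float = 0.5,
                                  **fit_kwargs) -> Posterior:
    """Joint model with a Gaussian longitudinal submodel.

    Counts are normalized to relative abundances, shifted by
    ``pseudocount`` reads to handle zeros, and log-transformed; the
    fitted log relative abundance enters the hazard linearly.  Structure
    and priors otherwise match the NB joint model.
    """
    return fit_joint(dataset, link="gaussian", pseudocount=pseudocount,
                     **fit_kwargs)


def event_free_scores(fit, dataset: JointDataset, landmark: float,
                      t_max: float = 10.0, seed: int = 0,
                      max_draws: int | None = 200,
                      n_steps: int = 200) -> pd.DataFrame:
    """Risk scores 1 - S_hat(t_max | data <= landmark) for at-risk subjects.

    ``fit`` is a :class:`Posterior` (joint models) or
    :class:`CoxComparator`.  Subjects at risk at the landmark (T >
    landmark) are scored; the outcome is the event-by-t_max indicator.
    """
    ev = dataset.events_frame()
    at_risk = ev[ev["event_time"] > landmark].reset_index(drop=True)
    if isinstance(fit, CoxComparator):
        S = fit.predict_event_free(at_risk[fit.w_names], t_max,
                                   landmark=landmark)
        scores = 1.0 - S
    else:
        scores = np.empty(len(at_risk))
        for k, subj in enumerate(at_risk["subject_id"]):
            pred = predict_event_free(fit, dataset, subj, landmark,
                                      [t_max], seed=seed + k,
                                      max_draws=max_draws, n_steps=n_steps,
                                      require_data=False)
            scores[k] = 1.0 - float(pred.S_draws[:, 0].mean())
    return pd.DataFrame({"subject_id": at_risk["subject_id"],
                         "score": scores,
                         "outcome": at_risk["status"].astype(int)})


def compare_models(config: SimulationConfig, landmarks=(1, 2, 4, 8),
                   alphas=(0.1, 0.5, 1.0), seed: int = 0,
                   fit_kwargs: dict | None = None,
                   prediction_draws: int = 200) -> pd.DataFrame:
    """AUC table over effect sizes and landmarks for the three models.

    For each alpha one dataset is simulated; the NB joint model, the
    Gaussian joint model and the Cox model are fitted to it, and each is
    scored at every landmark.  Returns a tidy frame with columns
    (alpha, landmark, model, auc, n_at_risk).
    """
    fit_kwargs = dict(fit_kwargs or {})
    rows = []
    for a_i, alpha in enumerate(alphas):
        cfg = dataclasses.replace(config, alpha=float(alpha))
        dataset, _ = simulate_joint_dataset(cfg, seed=seed + 1000 * a_i)
        fits = {
            "nb_joint": fit_joint(dataset, phi=cfg.phi, seed=seed + 1,
                                  **fit_kwargs),
            "gaussian_joint": fit_gaussian_joint_comparator(
                dataset, phi=cfg.phi, seed=seed + 2, **fit_kwargs),
            "cox": fit_cox_comparator(dataset.events),
        }
        for landmark in landmarks:
            for name, fit in fits.items():
                sc = event_free_scores(fit, dataset, landmark,
                                       t_max=cfg.t_max, seed=seed + 3,
                                       max_draws=prediction_draws)
                roc = roc_auc(sc["score"], sc["outcome"], landmark=landmark,
                              generator_alpha=alpha)
                rows.append({"alpha": alpha, "landmark": landmark,
                             "model": name, "auc": roc.auc,
                             "n_at_risk": len(sc)})
    return pd.DataFrame(rows)


def plot_auc_table(table: pd.DataFrame, path=None):
    """Line plot of AUC vs effect size per model and landmark.

    ``table`` is the tidy frame from :func:`compare_models`; returns the
    matplotlib figure (saved to ``path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    landmarks = sorted(table["landmark"].unique())
    fig, axes = plt.subplots(1, len(landmarks), sharey=True,
                             figsize=(3.2 * len(landmarks), 3.2))
    axes = np.atleast_1d(axes)
    for ax, lm in zip(axes, landmarks):
        sub = table[table["landmark"] == lm]
        for model, grp in sub.groupby("model"):
            grp = grp.sort_values("alpha")
            ax.plot(grp["alpha"], grp["auc"], marker="o", label=model)
        ax.axhline(0.5, color="grey", lw=0.8, ls="--")
        ax.set_title(f"data up to t = {lm:g}")
        ax.set_xlabel("effect size alpha")
    axes[0].set_ylabel("AUC")
    axes[-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def recovery_grid(N_set=(50, 100, 1000), K_set=(3, 5, 10),
                  replicates: int = 100,
                  config_template: SimulationConfig | None = None,
                  seed: int = 0, alpha_range=(0.1, 0.9),
                  fit_kwargs: dict | None = None) -> RecoveryGridResult:
    """Recovery of alpha over an N x K grid of study sizes.

    Per replicate a generating alpha is drawn uniformly from
    ``alpha_range`` (the same draw is reused in every grid cell, so cells
    differ only in study size); the squared error of the posterior median
    alpha is aggregated to a per-cell MSE.  Individual fit failures are
    logged and excluded, with the count reported.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates per cell")
    cfg0 = config_template or SimulationConfig()
    fit_kwargs = dict(fit_kwargs or {})
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(*alpha_range, size=replicates)
    err_rows = []
    for r in range(replicates):
        for N in N_set:
            for K in K_set:
                cfg = dataclasses.replace(cfg0, n_subjects=int(N),
                                          k_samples=int(K),
                                          alpha=float(alphas[r]))
                sim_seed = int(rng.integers(2 ** 31 - 1))
                try:
                    dataset, truth = simulate_joint_dataset(cfg, seed=sim_seed)
                    post = fit_joint(dataset, phi=cfg.phi, seed=sim_seed,
                                     **fit_kwargs)
                    err = post.median("alpha") - cfg.alpha
                    err_rows.append({"replicate": r, "N": N, "K": K,
                                     "alpha_true": cfg.alpha,
                                     "error": float(err), "failed": False})
                except Exception as exc:  # individual failures excluded
                    logger.warning("recovery fit failed (N=%s K=%s rep=%s): %s",
                                   N, K, r, exc)
                    err_rows.append({"replicate": r, "N": N, "K": K,
                                     "alpha_true": cfg.alpha,
                                     "error": np.nan, "failed": True})
    errors = pd.DataFrame(err_rows)
    rows = []
    for (N, K), grp in errors.groupby(["N", "K"]):
        ok = grp[~grp["failed"]]
        rows.append({"N": N, "K": K, "replicates": len(grp),
                     "n_failed": int(grp["failed"].sum()),
                     "mse": float(np.mean(ok["error"] ** 2)) if len(ok)
                     else np.nan})
    return RecoveryGridResult(table=pd.DataFrame(rows), errors=errors)
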