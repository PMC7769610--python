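"""Dynamic posterior predictions for trajectories and event-free probabilities.

Predictions for a subject condition on that subject's longitudinal data
up to a landmark time t and on being event-free at t.  For each retained
posterior draw the subject's random effects are refreshed from their
conditional distribution

    p(b_i | y_i(<= t), T_i > t, draw)  propto
        NB-lik(y_i | b_i) * exp(-H_i(t | b_i)) * MVN(b_i; 0, D)

with a short adaptive Metropolis chain, after which the longitudinal
trajectory p(u) = exp(x(u)'beta + z(u)'b_i) and the conditional
event-free probability S(u | T > t) = exp(-(H(u) - H(t))) are evaluated
per draw and summarized across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import Posterior, hdi
from .hazard import QuadratureRule
from .io_data import JointDataset

__all__ = ["DynamicPrediction", "refresh_random_effects",
           "predict_trajectory", "predict_event_free"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class DynamicPrediction:
    """Summarized conditional event-free probabilities for one subject."""

    subject_id: str
    landmark: float
    horizons: np.ndarray
    S_draws: np.ndarray          # (n_draws, n_horizons)
    summary: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            rows = []
            for j, u in enumerate(self.horizons):
                s = self.S_draws[:, j]
                lo80, hi80 = hdi(s, 0.8, min_draws=10)
                lo95, hi95 = hdi(s, 0.95, min_draws=10)
                rows.append({"horizon": float(u),
                             "median": float(np.median(s)),
                             "mean": float(np.mean(s)),
                             "hdi80_lo": lo80, "hdi80_hi": hi80,
                             "hdi95_lo": lo95, "hdi95_hi": hi95})
            self.summary = pd.DataFrame(rows)


class _SubjectContext:
    """Per-subject slices and posterior-draw arrays used by prediction."""

    def __init__(self, posterior: Posterior, dataset: JointDataset,
                 subject_id: str, landmark: float, max_draws: int | None,
                 require_data: bool = True):
        series = dataset.series
        frame = series.frame
        mask = (frame["subject_id"] == subject_id).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown subject {subject_id!r}")
        keep = mask & (frame["time"].to_numpy() <= landmark + 1e-12)
        if not keep.any() and require_data:
            raise ValueError(
                f"subject {subject_id!r} has no observations at or before "
                f"the landmark t={landmark}")
        self.y = frame.loc[keep, "y"].to_numpy(dtype=float)
        self.logC = np.log(frame.loc[keep, "C"].to_numpy(dtype=float))
        self.X = series.design_fixed[keep]
        self.Z = series.design_random[keep]
        self.covariates = series.subject_covariates(subject_id)
        ev = {e.subject_id: e for e in dataset.events}[subject_id]
        self.w = np.array([ev.covariates[n] for n in ev.covariates])
        self.formula = series.formula
        self.landmark = float(landmark)
        self.posterior = posterior
        self.phi = posterior.phi
        self.link = posterior.link
        self.baseline = posterior.baseline
        self.rule = QuadratureRule.gauss_legendre()
        if self.link == "gaussian":
            self.v = np.log((self.y + 0.5) / np.exp(self.logC))

        def flat(name):
            return posterior.stacked(name)

        names = posterior.names
        beta_names = [n for n in names if n.startswith("beta[")]
        gamma_names = [n for n in names if n.startswith("gamma[")]
        tau_names = [n for n in names if n.startswith("tau[")]
        nd = len(flat("alpha"))
        sel = np.arange(nd)
        if max_draws is not None and nd > max_draws:
            sel = np.linspace(0, nd - 1, max_draws).astype(int)
        self.sel = sel
        self.beta = np.column_stack([flat(n)[sel] for n in beta_names])
        self.gamma = (np.column_stack([flat(n)[sel] for n in gamma_names])
                      if gamma_names else np.zeros((len(sel), 0)))
        self.alpha = flat("alpha")[sel]
        self.lam = flat("lambda")[sel]
        self.shape = flat("shape")[sel] if "shape" in names else np.ones(len(sel))
        self.disp = flat("theta" if self.link == "nb" else "sigma")[sel]
        self.tau = np.column_stack([flat(n)[sel] for n in tau_names])
        self.q = self.tau.shape[1]
        self.rho = flat("rho")[sel] if "rho" in names else np.zeros(len(sel))
        self.wlin = self.gamma @ self.w if self.w.size else np.zeros(len(sel))

    def designs_at(self, times) -> tuple[np.ndarray, np.ndarray]:
        return self.formula.design_at_times(times, self.covariates)

    # -- draw-vectorized model pieces -------------------------------------
    def loglik_long(self, B: np.ndarray) -> np.ndarray:
        """(n_draws,) longitudinal log-lik of the subject's data given b."""
        eta_nooff = self.beta @ self.X.T + B @ self.Z.T   # (nd, k)
        if self.link == "nb":
            from scipy.special import gammaln
            th = self.disp[:, None]
            eta = np.clip(eta_nooff + self.logC, -500, 500)
            mu = np.exp(eta)
            log_denom = np.log(mu + th)
            ll = (gammaln(self.y + th) - gammaln(th) - gammaln(self.y + 1.0)
                  + th * (np.log(th) - log_denom) + self.y * (eta - log_denom))
        else:
            sg = self.disp[:, None]
            ll = -0.5 * ((self.v - eta_nooff) / sg) ** 2 - np.log(sg) \
                - 0.5 * _LOG2PI
        return ll.sum(axis=1)

    def cum_hazard(self, B: np.ndarray, t: float) -> np.ndarray:
        """(n_draws,) cumulative hazard H(t) given b."""
        if t <= 0:
            return np.zeros(len(B))
        nodes = t * self.rule.nodes
        Xg, Zg = self.designs_at(nodes)
        m = self.beta @ Xg.T + B @ Zg.T                   # (nd, Q)
        if self.link == "nb":
            g = self.alpha[:, None] * self.phi * np.exp(np.clip(m, -500, 30))
        else:
            g = self.alpha[:, None] * m
        if self.baseline == "exponential":
            h0 = self.lam[:, None] * np.ones_like(nodes)
        else:
            h0 = (self.lam * self.shape)[:, None] * \
                nodes[None, :] ** (self.shape[:, None] - 1.0)
        integ = h0 * np.exp(np.clip(g, -500, 300))
        return np.exp(self.wlin) * t * (integ @ self.rule.weights)

    def logprior_b(self, B: np.ndarray) -> np.ndarray:
        t0 = self.tau[:, 0]
        z1 = B[:, 0] / t0
        lp = -0.5 * z1 ** 2 - np.log(t0)
        if self.q == 2:
            t1, rho = self.tau[:, 1], self.rho
            s = np.sqrt(np.clip(1 - rho ** 2, 1e-12, None))
            z2 = (B[:, 1] / t1 - rho * z1) / s
            lp = lp - 0.5 * z2 ** 2 - np.log(t1) - np.log(s)
        return lp - 0.5 * self.q * _LOG2PI

    def log_target(self, B: np.ndarray) -> np.ndarray:
        out = (self.loglik_long(B) - self.cum_hazard(B, self.landmark)
               + self.logprior_b(B))
        return np.nan_to_num(out, nan=-np.inf)


def refresh_random_effects(posterior: Posterior, dataset: JointDataset,
                           subject_id: str, landmark: float,
                           n_steps: int = 200, seed: int = 0,
                           max_draws: int | None = 200,
                           _ctx: "_SubjectContext | None" = None
                           ) -> np.ndarray:
    """Per-draw conditional random effects b_i | data(<=t), T > t.

    Runs a short adaptive Metropolis chain per posterior draw (vectorized
    across draws); returns a (n_draws, q) array aligned with the draw
    subset used (``max_draws`` evenly spaced draws when thinning).
    """
    ctx = _ctx or _SubjectContext(posterior, dataset, subject_id, landmark,
                                  max_draws)
    rng = np.random.default_rng(seed)
    nd, q = len(ctx.alpha), ctx.q
    B = np.zeros((nd, q))
    lp = ctx.log_target(B)
    log_s = np.log(1.0)
    for step in range(n_steps):
        prop = B + np.exp(log_s) * ctx.tau * rng.standard_normal((nd, q))
        lp_prop = ctx.log_target(prop)
        a = np.exp(np.minimum(lp_prop - lp, 0.0))
        acc = rng.uniform(size=nd) < a
        B[acc] = prop[acc]
        lp = np.where(acc, lp_prop, lp)
        if step < n_steps // 2:
            log_s += (step + 1) ** -0.6 * (float(a.mean()) - 0.35)
    return B


def predict_trajectory(posterior: Posterior, dataset: JointDataset,
                       subject_id: str, landmark: float, grid,
                       n_steps: int = 200, seed: int = 0,
                       max_draws: int | None = 200) -> pd.DataFrame:
    """Pointwise posterior trajectory of the relative abundance p(u).

    Returns a frame with the median, mean and 80/95% HDI bands of
    p(u) = exp(x(u)'beta + z(u)'b_i) over the requested grid, using
    random effects refreshed from data up to the landmark.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        return pd.DataFrame(columns=["time", "median", "mean", "hdi80_lo",
                                     "hdi80_hi", "hdi95_lo", "hdi95_hi"])
    ctx = _SubjectContext(posterior, dataset, subject_id, landmark, max_draws)
    B = refresh_random_effects(posterior, dataset, subject_id, landmark,
                               n_steps=n_steps, seed=seed,
                               max_draws=max_draws, _ctx=ctx)
    Xg, Zg = ctx.designs_at(grid)
    logp = ctx.beta @ Xg.T + B @ Zg.T
    p = np.exp(np.clip(logp, -500, 50))
    rows = []
    for j, u in enumerate(grid):
        lo80, hi80 = hdi(p[:, j], 0.8, min_draws=10)
        lo95, hi95 = hdi(p[:, j], 0.95, min_draws=10)
        rows.append({"time": float(u), "median": float(np.median(p[:, j])),
                     "mean": float(np.mean(p[:, j])),
                     "hdi80_lo": lo80, "hdi80_hi": hi80,
                     "hdi95_lo": lo95, "hdi95_hi": hi95})
    return pd.DataFrame(rows)


def predict_event_free(posterior: Posterior, dataset: JointDataset,
                       subject_id: str, landmark: float, horizons,
                       n_steps: int = 200, seed: int = 0,
                       max_draws: int | None = 200,
                       require_data: bool = True) -> DynamicPrediction:
    """Conditional event-free probabilities S(u | T > t, data <= t).

    With ``require_data=False`` a subject without samples before the
    landmark is scored from covariates and survival-to-t alone (the
    random effects then condition only on T > t).
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < landmark - 1e-12):
        raise ValueError("every horizon must be >= the landmark time")
    ctx = _SubjectContext(posterior, dataset, subject_id, landmark, max_draws,
                          require_data=require_data)
    B = refresh_random_effects(posterior, dataset, subject_id, landmark,
                               n_steps=n_steps, seed=seed,
                               max_draws=max_draws, _ctx=ctx)
    Ht = ctx.cum_hazard(B, landmark)
    S = np.empty((len(B), len(horizons)))
    for j, u in enumerate(horizons):
        S[:, j] = np.exp(-(ctx.cum_hazard(B, float(u)) - Ht))
    S = np.clip(S, 0.0, 1.0)
    return DynamicPrediction(subject_id=subject_id, landmark=float(landmark),
                             horizons=horizons, S_draws=S)
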