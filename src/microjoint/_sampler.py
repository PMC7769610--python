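"""Hamiltonian Monte Carlo for the joint posterior.

The sampler works on the concatenated unconstrained state
psi = (zeta, u.ravel()) — global parameters plus non-centered random
effects — using the model's analytic gradients.  Warmup adapts the step
size by dual averaging toward a target acceptance of 0.8 and a diagonal
mass matrix from the draw variances in two adaptation windows; both are
frozen after warmup so the kept draws target the exact posterior.  The
number of leapfrog steps is jittered uniformly up to ``max_leapfrog`` to
avoid resonances.  Trajectories whose energy error exceeds 1000 are
counted as divergences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["run_chain"]


def run_chain(model, zeta0, u0, *, warmup, n_keep, thin=1, max_leapfrog=32,
              target_accept=0.8, rng=None):
    """One HMC chain; returns (zeta draws, b draws, diagnostics)."""
    rng = np.random.default_rng(rng)
    zeta = np.asarray(zeta0, dtype=float)
    u = np.asarray(u0, dtype=float)
    d = model.dim
    N, q = u.shape
    D = d + N * q

    def split(psi):
        return psi[:d], psi[d:].reshape(N, q)

    def vg(psi):
        val, gz, gu = model.value_and_grad(*split(psi))
        return val, np.concatenate([gz, gu.ravel()])

    psi = np.concatenate([zeta, u.ravel()])
    val, grad = vg(psi)
    if not np.isfinite(val):
        raise RuntimeError("initial state has non-finite log posterior")

    inv_mass = np.ones(D)
    # dual averaging (Hoffman & Gelman) state; restarted when the mass
    # matrix changes so the final step size matches the final metric
    log_eps = np.log(0.1 / D ** 0.25)
    mu_da = np.log(10.0) + log_eps
    log_eps_bar, h_bar = log_eps, 0.0
    t_da = 0
    t0_da, kappa, gamma_da = 10.0, 0.75, 0.05

    # mass adaptation windows within warmup
    w1, w2 = int(warmup * 0.4), int(warmup * 0.8)
    acc_sum = np.zeros(D); acc_sq = np.zeros(D); acc_n = 0

    keep_zeta = np.empty((n_keep, d))
    keep_b = np.empty((n_keep, N, q))
    n_div = 0
    accepts = 0.0; n_post = 0

    n_iter = warmup + n_keep * thin
    for it in range(n_iter):
        in_warmup = it < warmup
        eps = float(np.exp(log_eps if in_warmup else log_eps_bar))
        L = int(rng.integers(1, max_leapfrog + 1))
        mom = rng.standard_normal(D) / np.sqrt(inv_mass)
        H0 = -val + 0.5 * np.sum(inv_mass * mom ** 2)

        p_psi, p_mom, p_grad = psi.copy(), mom.copy(), grad.copy()
        p_val = val
        diverged = False
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(L):
                p_mom = p_mom + 0.5 * eps * p_grad
                p_psi = p_psi + eps * inv_mass * p_mom
                if not np.all(np.isfinite(p_psi)):
                    diverged = True
                    break
                p_val, p_grad = vg(p_psi)
                if not np.isfinite(p_val):
                    diverged = True
                    break
                p_mom = p_mom + 0.5 * eps * p_grad
            if diverged:
                a = 0.0
                n_div += 1
            else:
                H1 = -p_val + 0.5 * np.sum(inv_mass * p_mom ** 2)
                dH = H1 - H0
                if dH > 1000.0:
                    n_div += 1
                a = float(np.exp(min(-dH, 0.0))) if np.isfinite(dH) else 0.0
        if rng.uniform() < a:
            psi, val, grad = p_psi, p_val, p_grad

        if in_warmup:
            # dual averaging on the acceptance statistic
            t_da += 1
            h_bar = (1 - 1 / (t_da + t0_da)) * h_bar \
                + (target_accept - a) / (t_da + t0_da)
            log_eps = mu_da - np.sqrt(t_da) / gamma_da * h_bar
            eta_da = t_da ** -kappa
            log_eps_bar = eta_da * log_eps + (1 - eta_da) * log_eps_bar
            if w1 <= it < w2:
                acc_sum += psi; acc_sq += psi ** 2; acc_n += 1
            if it == w2 - 1 and acc_n > 10:
                var = acc_sq / acc_n - (acc_sum / acc_n) ** 2
                inv_mass = np.clip(var, 1e-8, 1e3)
                # restart the step-size search under the new metric
                mu_da = np.log(10.0) + log_eps
                h_bar, t_da = 0.0, 0
                log_eps_bar = log_eps
        else:
            accepts += a; n_post += 1
            k = it - warmup
            if k % thin == thin - 1:
                zeta_k, u_k = split(psi)
                kk = k // thin
                keep_zeta[kk] = zeta_k
                keep_b[kk] = model.b_from(model.unpack(zeta_k), u_k)

    diag = {"accept_mean": accepts / max(n_post, 1),
            "step_size": float(np.exp(log_eps_bar)),
            "n_divergent": int(n_div)}
    return keep_zeta, keep_b, diag
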