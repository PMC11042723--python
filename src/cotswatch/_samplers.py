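"""MCMC engines behind the hierarchical models.

Two samplers cover every model in the package:

* :func:`gibbs_lmm` — blocked Gibbs for the Gaussian linear mixed model with
  a cell-means fixed design and one grouped random intercept.  All full
  conditionals are conjugate (normal coefficients, inverse-gamma variances),
  so the sampler mixes essentially immediately at the pipeline's default
  settings (3 chains x 4000 iterations, 1000 burn-in, thin 5).
* :func:`mh_beta_glmm` — adaptive Metropolis-within-Gibbs for the beta GLMM
  on ordinal-cover midpoints (logit link; year cell effects, reef random
  intercepts, an observation-level random intercept, and a precision
  parameter).  Year, reef, and observation blocks factorise over the data,
  so proposals are vectorised and accepted element-wise.

Both samplers are deterministic given their seed and return draws shaped
``(chains, draws)`` per parameter, ready for split-R-hat diagnostics.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, expit

# weakly-informative defaults: N(0, 2.5^2) fixed effects on the standardized
# scale; InvGamma(2, 1) variances (prior mean 1 on the standardized scale)
PRIOR_BETA_SD = 2.5
PRIOR_VAR_SHAPE = 2.0
PRIOR_VAR_SCALE = 1.0

MCMC_DEFAULTS = {"chains": 3, "iterations": 4000, "burn_in": 1000, "thin": 5}


def _mcmc_plan(mcmc: dict | None) -> tuple[int, int, int, int]:
    m = {**MCMC_DEFAULTS, **(mcmc or {})}
    return m["chains"], m["iterations"], m["burn_in"], m["thin"]


def gibbs_lmm(
    y: np.ndarray,
    cell_index: np.ndarray,
    group_index: np.ndarray,
    n_cells: int,
    n_groups: int,
    mcmc: dict | None = None,
    seed: int = 0,
) -> dict:
    """Gaussian mixed model  y_i = beta[cell_i] + u[group_i] + eps_i.

    The response is standardized internally; returned draws are on the
    original scale.  Returns ``beta`` (chains, draws, n_cells), ``sigma_u``
    and ``sigma_eps`` (chains, draws).
    """
    chains, iterations, burn_in, thin = _mcmc_plan(mcmc)
    y = np.asarray(y, dtype=float)
    n = y.size
    mu_y, sd_y = float(np.mean(y)), float(np.std(y))
    if sd_y == 0:
        sd_y = 1.0
    ys = (y - mu_y) / sd_y

    cell_index = np.asarray(cell_index)
    group_index = np.asarray(group_index)
    if np.any(np.bincount(cell_index, minlength=n_cells) == 0):
        raise ValueError("every cell must contain at least one observation")

    # stacked design [cells | groups]; the coefficient block is drawn jointly,
    # which removes the location ridge between cell means and group intercepts
    p = n_cells + n_groups
    w = np.zeros((n, p))
    w[np.arange(n), cell_index] = 1.0
    w[np.arange(n), n_cells + group_index] = 1.0
    wtw = w.T @ w
    wty = w.T @ ys

    keep = (iterations - burn_in) // thin
    out_beta = np.empty((chains, keep, n_cells))
    out_su = np.empty((chains, keep))
    out_se = np.empty((chains, keep))

    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        var_u, var_e = 1.0, 1.0
        k = 0
        for it in range(iterations):
            # (beta, u) | variances: joint multivariate normal
            prior_prec = np.concatenate(
                [np.full(n_cells, 1.0 / PRIOR_BETA_SD**2),
                 np.full(n_groups, 1.0 / var_u)]
            )
            prec = wtw / var_e + np.diag(prior_prec)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(
                chol.T, np.linalg.solve(chol, wty / var_e)
            )
            coef = mean + np.linalg.solve(chol.T, rng.standard_normal(p))
            beta, u = coef[:n_cells], coef[n_cells:]
            # variances | coefficients: conjugate inverse-gamma
            var_u = 1.0 / rng.gamma(
                PRIOR_VAR_SHAPE + 0.5 * n_groups,
                1.0 / (PRIOR_VAR_SCALE + 0.5 * float(u @ u)),
            )
            eps = ys - w @ coef
            var_e = 1.0 / rng.gamma(
                PRIOR_VAR_SHAPE + 0.5 * n,
                1.0 / (PRIOR_VAR_SCALE + 0.5 * float(eps @ eps)),
            )
            if it >= burn_in and (it - burn_in) % thin == 0:
                out_beta[c, k] = mu_y + sd_y * beta
                out_su[c, k] = sd_y * np.sqrt(var_u)
                out_se[c, k] = sd_y * np.sqrt(var_e)
                k += 1
    return {"beta": out_beta, "sigma_u": out_su, "sigma_eps": out_se}


def _beta_loglik(logit_mu, phi, log_y, log1m_y):
    mu = expit(logit_mu)
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * log_y + (b - 1.0) * log1m_y - betaln(a, b)


def mh_beta_glmm(
    y: np.ndarray,
    year_index: np.ndarray,
    reef_index: np.ndarray,
    n_years: int,
    n_reefs: int,
    mcmc: dict | None = None,
    seed: int = 0,
) -> dict:
    """Beta GLMM  y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi),
    logit(mu_i) = a[year_i] + u[reef_i] + e_i.

    ``y`` must already be compressed off the closed unit interval.  Returns
    ``a`` (chains, draws, n_years) on the logit scale plus ``sigma_u``,
    ``sigma_e``, ``phi`` draws.
    """
    chains, iterations, burn_in, thin = _mcmc_plan(mcmc)
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta responses must lie strictly inside (0, 1)")
    n = y.size
    log_y, log1m_y = np.log(y), np.log1p(-y)
    year_index = np.asarray(year_index)
    reef_index = np.asarray(reef_index)
    n_per_reef = np.bincount(reef_index, minlength=n_reefs).astype(float)

    keep = (iterations - burn_in) // thin
    out_a = np.empty((chains, keep, n_years))
    out_su = np.empty((chains, keep))
    out_se = np.empty((chains, keep))
    out_phi = np.empty((chains, keep))

    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        # moment-based start near the empirical year means
        year_means = np.bincount(year_index, weights=y, minlength=n_years)
        year_means /= np.maximum(np.bincount(year_index, minlength=n_years), 1)
        year_means = np.clip(year_means, 0.02, 0.98)
        a = np.log(year_means / (1 - year_means)) + rng.normal(0, 0.1, n_years)
        u = rng.normal(0, 0.1, n_reefs)
        e = rng.normal(0, 0.1, n)
        var_u, var_e = 0.1, 0.05
        log_phi = np.log(30.0) + rng.normal(0, 0.2)
        steps = {"a": 0.1, "u": 0.1, "e": 0.3, "phi": 0.1}
        acc = {k: 0 for k in steps}
        tries = {k: 0 for k in steps}
        k_out = 0
        for it in range(iterations):
            phi = np.exp(log_phi)
            eta = a[year_index] + u[reef_index] + e

            # year effects: block factorises over years
            prop = rng.normal(0, steps["a"], n_years)
            ll_cur = _beta_loglik(eta, phi, log_y, log1m_y)
            ll_new = _beta_loglik(eta + prop[year_index], phi, log_y, log1m_y)
            delta = np.bincount(year_index, weights=ll_new - ll_cur, minlength=n_years)
            delta += ((a**2) - (a + prop) ** 2) / (2 * PRIOR_BETA_SD**2)
            accept = np.log(rng.uniform(size=n_years)) < delta
            a = np.where(accept, a + prop, a)
            acc["a"] += accept.mean()
            tries["a"] += 1
            eta = a[year_index] + u[reef_index] + e

            # reef intercepts: factorises over reefs
            prop = rng.normal(0, steps["u"], n_reefs)
            ll_cur = _beta_loglik(eta, phi, log_y, log1m_y)
            ll_new = _beta_loglik(eta + prop[reef_index], phi, log_y, log1m_y)
            delta = np.bincount(reef_index, weights=ll_new - ll_cur, minlength=n_reefs)
            delta += ((u**2) - (u + prop) ** 2) / (2 * var_u)
            accept = np.log(rng.uniform(size=n_reefs)) < delta
            u = np.where(accept, u + prop, u)
            acc["u"] += accept.mean()
            tries["u"] += 1
            eta = a[year_index] + u[reef_index] + e

            # observation-level intercepts: factorises over observations
            prop = rng.normal(0, steps["e"], n)
            ll_cur = _beta_loglik(eta, phi, log_y, log1m_y)
            ll_new = _beta_loglik(eta + prop, phi, log_y, log1m_y)
            delta = ll_new - ll_cur + ((e**2) - (e + prop) ** 2) / (2 * var_e)
            accept = np.log(rng.uniform(size=n)) < delta
            e = np.where(accept, e + prop, e)
            acc["e"] += accept.mean()
            tries["e"] += 1
            eta = a[year_index] + u[reef_index] + e

            # variances: conjugate inverse-gamma
            var_u = 1.0 / rng.gamma(
                PRIOR_VAR_SHAPE + 0.5 * n_reefs,
                1.0 / (0.1 + 0.5 * float(u @ u)),
            )
            var_e = 1.0 / rng.gamma(
                PRIOR_VAR_SHAPE + 0.5 * n,
                1.0 / (0.1 + 0.5 * float(e @ e)),
            )

            # likelihood-invariant location swaps: shift all year effects by
            # delta and the reef (resp. observation) intercepts by -delta.
            # eta is unchanged, so acceptance depends on the priors alone;
            # these moves break the additive ridge between the blocks.
            for other, var_other in (("u", var_u), ("e", var_e)):
                vec = u if other == "u" else e
                delta = rng.normal(0, 1.5 * np.sqrt(var_other / vec.size))
                dlp = (
                    (np.sum(a**2) - np.sum((a + delta) ** 2))
                    / (2 * PRIOR_BETA_SD**2)
                    + (np.sum(vec**2) - np.sum((vec - delta) ** 2))
                    / (2 * var_other)
                )
                if np.log(rng.uniform()) < dlp:
                    a = a + delta
                    if other == "u":
                        u = vec - delta
                    else:
                        e = vec - delta

            # precision: MH on the log scale, Gamma(2, rate 0.05) prior
            lp_prop = log_phi + rng.normal(0, steps["phi"])
            ll_cur = _beta_loglik(eta, phi, log_y, log1m_y).sum()
            ll_new = _beta_loglik(eta, np.exp(lp_prop), log_y, log1m_y).sum()
            # log prior (incl. Jacobian of the log transform)
            pr_cur = 2 * log_phi - 0.05 * phi
            pr_new = 2 * lp_prop - 0.05 * np.exp(lp_prop)
            if np.log(rng.uniform()) < ll_new + pr_new - ll_cur - pr_cur:
                log_phi = lp_prop
                acc["phi"] += 1
            tries["phi"] += 1

            # step-size adaptation during burn-in only
            if it < burn_in and (it + 1) % 100 == 0:
                for key in steps:
                    rate = acc[key] / tries[key]
                    steps[key] *= np.exp(0.5 * (rate - 0.4))
                    acc[key] = 0
                    tries[key] = 0

            if it >= burn_in and (it - burn_in) % thin == 0:
                out_a[c, k_out] = a
                out_su[c, k_out] = np.sqrt(var_u)
                out_se[c, k_out] = np.sqrt(var_e)
                out_phi[c, k_out] = np.exp(log_phi)
                k_out += 1
    return {"a": out_a, "sigma_u": out_su, "sigma_e": out_se, "phi": out_phi}
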