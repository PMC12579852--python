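"""MCMC engines for the mixed models.

Two samplers share one parameterization: fixed effects ``beta`` (the TL and
BAI columns of the design matrix are functions of latent per-unit true
values), individual random intercepts ``u`` with sd ``sigma_u``, latent TL /
BAI values with independent normal measurement priors, and for the Gaussian
family a residual sd ``sigma``.

- Gaussian (log response): full conditionals for beta, u, and the latent
  covariates are normal, so those are Gibbs updates; the two sds use slice
  sampling (Exponential priors are not conjugate).
- Poisson (log link, optionally zero-truncated): beta uses an adaptive
  random-walk Metropolis block (proposal covariance learned during warmup);
  u and the latent covariates use vectorized per-unit Metropolis steps
  (units are conditionally independent); sigma_u uses slice sampling.

Chains are seeded from ``(seed, chain)`` via numpy SeedSequence spawning, so
runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["run_chain_gaussian", "run_chain_poisson", "slice_sample"]


def slice_sample(x0: float, logp, rng, w: float = 1.0, max_steps: int = 50):
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    logy = logp(x0) + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logp(left) < logy:
            break
        left -= w
    for _ in range(max_steps):
        if logp(right) < logy:
            break
        right += w
    for _ in range(100):
        x1 = left + (right - left) * rng.random()
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


class _LatentBlock:
    """Per-unit latent covariate (true TL or BAI) entering z-scored."""

    def __init__(self, col, unit_idx, prior_mean, prior_sd, mean, sd):
        self.col = col                      # design-matrix column index
        self.unit_idx = np.asarray(unit_idx)
        self.prior_mean = np.asarray(prior_mean, float)
        self.prior_sd = np.asarray(prior_sd, float)
        self.mean = mean                    # z-scoring constants
        self.sd = sd
        self.n_units = self.prior_mean.size
        self.value = self.prior_mean.copy()
        self.n_per_unit = np.bincount(self.unit_idx, minlength=self.n_units)
        self.active = bool(np.any(self.prior_sd > 0))

    def z(self):
        return (self.value[self.unit_idx] - self.mean) / self.sd


def _sd_logp_factory(values, rate):
    ss = float(np.sum(values ** 2))
    m = values.size

    def logp(x):            # x = log sd
        sd = np.exp(x)
        return -m * x - ss / (2.0 * sd * sd) - rate * sd + x

    return logp


def _prep(data, priors, rng):
    X = data.X.copy()
    n, p = X.shape
    widx = data.whale_idx
    n_whales = int(widx.max()) + 1 if n else 0
    blocks = []
    for block in data.latent_blocks():
        blk = _LatentBlock(**block)
        if blk.active:
            X[:, blk.col] = blk.z()
            blocks.append(blk)
    m0 = np.zeros(p)
    s0 = np.full(p, priors.slope_sd)
    icol = data.colnames.index("intercept")
    m0[icol] = priors.intercept_center
    s0[icol] = priors.intercept_sd
    return X, n, p, widx, n_whales, blocks, m0, s0


def run_chain_gaussian(data, priors, n_iter, warmup, rng, thin=1):
    y = np.asarray(data.y, float)
    X, n, p, widx, n_whales, blocks, m0, s0 = _prep(data, priors, rng)
    prior_prec = 1.0 / s0 ** 2

    beta = np.zeros(p)
    beta[data.colnames.index("intercept")] = priors.intercept_center
    u = np.zeros(n_whales)
    sigma = max(float(np.std(y - X @ beta)), 1e-3)
    sigma_u = 0.1

    keep = max(0, (n_iter - warmup) // thin)
    out_beta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_sigma_u = np.empty(keep)
    out_u = np.empty((keep, n_whales))
    out_var_fit = np.empty(keep)
    out_var_res = np.empty(keep)
    eta_mean = np.zeros(n)
    k = 0
    for it in range(n_iter):
        # beta | rest  (conjugate normal)
        r = y - u[widx]
        A = X.T @ X / sigma ** 2 + np.diag(prior_prec)
        b = X.T @ r / sigma ** 2 + m0 * prior_prec
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, b)
        beta = mu + np.linalg.solve(L.T, rng.standard_normal(p))

        # random intercepts | rest
        eta_fix = X @ beta
        ru = y - eta_fix
        if sigma_u > 0:
            prec = data.n_per_whale / sigma ** 2 + 1.0 / sigma_u ** 2
            mean_u = (np.bincount(widx, ru, minlength=n_whales)
                      / sigma ** 2) / prec
            u = mean_u + rng.standard_normal(n_whales) / np.sqrt(prec)
        else:
            u = np.zeros(n_whales)

        # residual sd (Exponential prior, slice in log space)
        resid = ru - u[widx]
        logsig = slice_sample(np.log(sigma),
                              _sd_logp_factory(resid, priors.sd_rate), rng)
        sigma = float(np.exp(logsig))

        # random-intercept sd, centered step ...
        logsu = slice_sample(np.log(max(sigma_u, 1e-6)),
                             _sd_logp_factory(u, priors.sd_rate), rng)
        sigma_u = float(np.exp(logsu))
        # ... interwoven with a non-centered step (u = sigma_u * u_tilde),
        # which avoids the slow centered mixing at small sigma_u
        if sigma_u > 0 and n_whales:
            utilde = u / sigma_u
            ut_obs = utilde[widx]

            def _logp_nc(x):
                s = np.exp(x)
                r_nc = ru - s * ut_obs
                return (-(r_nc @ r_nc) / (2.0 * sigma ** 2)
                        - priors.sd_rate * s + x)

            logsu = slice_sample(np.log(sigma_u), _logp_nc, rng, w=0.5)
            sigma_u = float(np.exp(logsu))
            u = utilde * sigma_u

        # latent covariates (conjugate: the model is linear in each latent)
        for blk in blocks:
            bcoef = beta[blk.col]
            a = bcoef / blk.sd
            partial = y - (eta_fix - bcoef * X[:, blk.col]) - u[widx]
            adj = partial + a * blk.mean
            fixed = blk.prior_sd == 0
            prec = np.where(
                fixed, np.inf,
                blk.n_per_unit * a * a / sigma ** 2
                + 1.0 / np.where(fixed, 1.0, blk.prior_sd) ** 2)
            num = (a * np.bincount(blk.unit_idx, adj, minlength=blk.n_units)
                   / sigma ** 2
                   + blk.prior_mean / np.where(fixed, 1.0, blk.prior_sd) ** 2)
            with np.errstate(invalid="ignore"):
                draw = num / prec + rng.standard_normal(blk.n_units) / np.sqrt(prec)
            blk.value = np.where(fixed, blk.prior_mean, draw)
            X[:, blk.col] = blk.z()
            eta_fix = X @ beta

        if it >= warmup and (it - warmup) % thin == 0:
            eta = eta_fix + u[widx]
            out_beta[k] = beta
            out_sigma[k] = sigma
            out_sigma_u[k] = sigma_u
            out_u[k] = u
            out_var_fit[k] = float(np.var(eta))
            out_var_res[k] = sigma ** 2
            eta_mean += eta
            k += 1
    if k:
        eta_mean /= k
    return {"beta": out_beta, "sigma_resid": out_sigma,
            "sigma_individual": out_sigma_u, "u": out_u,
            "var_fit": out_var_fit, "var_res": out_var_res,
            "eta_mean": eta_mean}


def _pois_loglik_terms(y, eta, truncated):
    lam = np.exp(eta)
    ll = y * eta - lam
    if truncated:
        ll -= np.log1p(-np.exp(-lam))
    return ll, lam


def run_chain_poisson(data, priors, n_iter, warmup, rng, thin=1,
                      truncated=True):
    y = np.asarray(data.y, float)
    X, n, p, widx, n_whales, blocks, m0, s0 = _prep(data, priors, rng)
    prior_prec = 1.0 / s0 ** 2

    beta = np.zeros(p)
    beta[data.colnames.index("intercept")] = priors.intercept_center
    u = np.zeros(n_whales)
    sigma_u = 0.1
    eta = X @ beta + u[widx]
    ll, lam = _pois_loglik_terms(y, eta, truncated)

    # adaptive RW state for the beta block
    scale = 0.1 / np.sqrt(p)
    chol_prop = np.eye(p)
    beta_bar = beta.copy()
    beta_cov = np.eye(p) * 1e-4
    s_u = 0.3
    s_blk = {id(blk): 0.5 * np.mean(blk.prior_sd[blk.prior_sd > 0])
             if np.any(blk.prior_sd > 0) else 0.1 for blk in blocks}

    keep = max(0, (n_iter - warmup) // thin)
    out_beta = np.empty((keep, p))
    out_sigma_u = np.empty(keep)
    out_u = np.empty((keep, n_whales))
    out_var_fit = np.empty(keep)
    out_var_res = np.empty(keep)
    out_chi2 = np.empty(keep)
    eta_mean = np.zeros(n)
    k = 0
    for it in range(n_iter):
        # ---- beta block: adaptive random-walk Metropolis
        step = scale * (chol_prop @ rng.standard_normal(p))
        beta_new = beta + step
        eta_new = eta + X @ step
        ll_new, lam_new = _pois_loglik_terms(y, eta_new, truncated)
        dprior = -0.5 * np.sum(((beta_new - m0) ** 2 - (beta - m0) ** 2)
                               * prior_prec)
        accept = np.log(rng.random()) < ll_new.sum() - ll.sum() + dprior
        if accept:
            beta, eta, ll, lam = beta_new, eta_new, ll_new, lam_new
        if it < warmup:
            # Robbins-Monro scale + empirical covariance adaptation
            scale *= np.exp(2.0 * (float(accept) - 0.234) / (1 + it) ** 0.6)
            w = 1.0 / (it + 2)
            delta = beta - beta_bar
            beta_bar += w * delta
            beta_cov = (1 - w) * (beta_cov + w * np.outer(delta, delta))
            if it >= 200 and it % 50 == 0:
                try:
                    chol_prop = np.linalg.cholesky(
                        2.38 ** 2 / p * (beta_cov + 1e-9 * np.eye(p)))
                    scale = 1.0
                except np.linalg.LinAlgError:
                    pass

        # ---- random intercepts: vectorized per-whale Metropolis
        if sigma_u > 0:
            u_new = u + s_u * rng.standard_normal(n_whales)
            eta_new = eta + (u_new - u)[widx]
            ll_new, lam_new = _pois_loglik_terms(y, eta_new, truncated)
            dll = np.bincount(widx, ll_new - ll, minlength=n_whales)
            dll += (u ** 2 - u_new ** 2) / (2.0 * sigma_u ** 2)
            acc = np.log(rng.random(n_whales)) < dll
            if acc.any():
                u = np.where(acc, u_new, u)
                eta = X @ beta + u[widx]
                ll, lam = _pois_loglik_terms(y, eta, truncated)
            if it < warmup:
                s_u *= np.exp(2.0 * (acc.mean() - 0.44) / (1 + it) ** 0.6)
        else:
            u = np.zeros(n_whales)

        # ---- latent covariates: vectorized per-unit Metropolis
        for blk in blocks:
            sprop = s_blk[id(blk)]
            val_new = blk.value + sprop * rng.standard_normal(blk.n_units)
            fixed = blk.prior_sd == 0
            val_new = np.where(fixed, blk.value, val_new)
            dz = (val_new - blk.value) / blk.sd
            eta_new = eta + beta[blk.col] * dz[blk.unit_idx]
            ll_new, lam_new = _pois_loglik_terms(y, eta_new, truncated)
            dll = np.bincount(blk.unit_idx, ll_new - ll,
                              minlength=blk.n_units)
            with np.errstate(divide="ignore", invalid="ignore"):
                dprior_u = ((blk.value - blk.prior_mean) ** 2
                            - (val_new - blk.prior_mean) ** 2) / (
                    2.0 * blk.prior_sd ** 2)
            dprior_u = np.where(fixed, -np.inf, dprior_u)
            acc = np.log(rng.random(blk.n_units)) < dll + dprior_u
            if acc.any():
                blk.value = np.where(acc, val_new, blk.value)
                X[:, blk.col] = blk.z()
                eta = X @ beta + u[widx]
                ll, lam = _pois_loglik_terms(y, eta, truncated)
            if it < warmup:
                frac = acc[~fixed].mean() if (~fixed).any() else 0.44
                s_blk[id(blk)] *= np.exp(
                    2.0 * (frac - 0.44) / (1 + it) ** 0.6)

        # ---- sigma_u (slice, Exponential prior), centered step ...
        logsu = slice_sample(np.log(max(sigma_u, 1e-6)),
                             _sd_logp_factory(u, priors.sd_rate), rng)
        sigma_u = float(np.exp(logsu))
        # ... interwoven with a non-centered step (u = sigma_u * u_tilde),
        # which decouples sigma_u from the random intercepts and fixes the
        # slow mixing of the centered parameterization at small sigma_u
        if sigma_u > 0 and n_whales:
            utilde = u / sigma_u
            eta_base = eta - u[widx]

            def _logp_nc(x):
                s = np.exp(x)
                ll_nc, _ = _pois_loglik_terms(
                    y, eta_base + s * utilde[widx], truncated)
                return ll_nc.sum() - priors.sd_rate * s + x

            logsu = slice_sample(np.log(sigma_u), _logp_nc, rng, w=0.5)
            sigma_u = float(np.exp(logsu))
            u = utilde * sigma_u
            eta = eta_base + u[widx]
            ll, lam = _pois_loglik_terms(y, eta, truncated)

        if it >= warmup and (it - warmup) % thin == 0:
            out_beta[k] = beta
            out_sigma_u[k] = sigma_u
            out_u[k] = u
            out_var_fit[k] = float(np.var(eta))
            out_var_res[k] = float(np.mean(1.0 / lam))
            out_chi2[k] = float(np.sum((y - lam) ** 2 / lam))
            eta_mean += eta
            k += 1
    if k:
        eta_mean /= k
    return {"beta": out_beta, "sigma_individual": out_sigma_u, "u": out_u,
            "var_fit": out_var_fit, "var_res": out_var_res,
            "pearson_chi2": out_chi2, "eta_mean": eta_mean}
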