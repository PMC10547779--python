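"""Adaptive Metropolis-within-Gibbs sampler for random-intercept GLMMs.

Model, per observation i with participant g(i)::

    gaussian:  y_i ~ Normal(x_i' beta + u_{g(i)}, sigma^2)
    poisson:   y_i ~ Poisson(exp(x_i' beta + u_{g(i)}))

    u_j ~ Normal(0, tau^2)

Priors (the conventions of standard Bayesian regression software):
non-intercept slopes Normal(0, 3) or
Cauchy(0, 3).  For the Poisson family (log link, responses are small
counts) the intercept is Student-t(3, 0, 2.5) and tau half-Student-t(3,
0, 2.5).  For the Gaussian family the same t(3) priors are centred and
scaled to the response, as the usual regression tools do internally:
intercept t(3, median(y), s_y), tau and sigma half-t(3, 0, s_y) with
s_y = max(2.5, mad(y)); 2.5 is the conventional floor of that scale.  A
zero-centred scale-2.5 intercept prior on a response living at a scale of
hundreds creates a spurious posterior mode (the random intercepts absorb
the offset), so the data-scaled convention is both what the reference
tool does and what keeps the posterior unimodal.

The two families use different kernels, both exact for the stated model:

gaussian
    The random intercepts are integrated out analytically (each group's
    marginal covariance is sigma^2 I + tau^2 11', inverted via
    Sherman-Morrison), leaving a (p + 2)-dimensional posterior over
    (beta, log tau, log sigma) sampled with a joint adaptive random-walk
    Metropolis (Haario-style covariance adaptation during warmup).  This
    sidesteps the tau-sigma funnel entirely — important here, where most
    participants contribute only two observations.  The u_j are then drawn
    exactly from their Normal conditional for each retained iteration.
poisson
    Metropolis-within-Gibbs: a joint adaptive random-walk on beta; one
    vectorised elementwise random-walk pass over the conditionally
    independent u_j; a location swap (beta_0, u) -> (beta_0 + d, u - d)
    that decorrelates the intercept from the random-intercept mean; a
    scale move (u, tau) -> (a u, a tau) that travels along the variance
    funnel; and a random-walk update of log tau.

Proposal scales adapt toward standard acceptance targets during warmup
only and are frozen afterwards, so the retained draws come from a fixed
transition kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["GlmmSampler", "SamplerSettings"]

_T3_SCALE = 2.5  # Student-t(3, 0, 2.5) for intercept / group sd


def _t_logpdf(x, df, scale):
    return -((df + 1) / 2) * np.log1p((x / scale) ** 2 / df)


def _normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2


def _cauchy_logpdf(x, scale):
    return -np.log1p((x / scale) ** 2)


@dataclass
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1


class GlmmSampler:
    """MCMC for one random-intercept GLMM on fixed data.

    Parameters
    ----------
    X : (n, p) design matrix, first column the intercept when present.
    y : (n,) response.
    groups : (n,) integer group codes in 0..J-1.
    family : "gaussian" or "poisson".
    intercept_index : column of X holding the intercept, or None.
    slope_prior : "normal" (default) or "cauchy", both with scale 3.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray,
        family: str,
        intercept_index: int | None = 0,
        slope_prior: str = "normal",
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.groups = np.asarray(groups, dtype=int)
        if family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {family!r}")
        if family == "poisson" and not np.all(np.mod(self.y, 1) == 0):
            raise ValueError("poisson responses must be integers")
        if family == "poisson" and np.any(self.y < 0):
            raise ValueError("poisson responses must be non-negative")
        self.family = family
        self.n, self.p = self.X.shape
        self.J = int(self.groups.max()) + 1
        self.intercept_index = intercept_index
        if slope_prior not in ("normal", "cauchy"):
            raise ValueError(f"unknown slope prior {slope_prior!r}")
        self.slope_prior = slope_prior
        if family == "gaussian":
            med = float(np.median(self.y))
            mad = 1.4826 * float(np.median(np.abs(self.y - med)))
            s_y = max(_T3_SCALE, mad)
            self.intercept_loc, self.intercept_scale = med, s_y
            self.tau_scale = self.sigma_scale = s_y
        else:
            self.intercept_loc, self.intercept_scale = 0.0, _T3_SCALE
            self.tau_scale = _T3_SCALE
            self.sigma_scale = _T3_SCALE  # unused
        # constant terms of the poisson loglik, kept so reported
        # log-posteriors are on the true scale
        self._pois_const = -float(np.sum(gammaln(self.y + 1))) if family == "poisson" else 0.0

    # --- log densities -------------------------------------------------
    def _row_loglik(self, eta, sigma):
        if self.family == "gaussian":
            r = self.y - eta
            return -0.5 * (r / sigma) ** 2 - np.log(sigma)
        return self.y * eta - np.exp(eta)

    def _beta_logprior(self, beta):
        lp = 0.0
        for k in range(self.p):
            if k == self.intercept_index:
                lp += _t_logpdf(beta[k] - self.intercept_loc, 3.0, self.intercept_scale)
            elif self.slope_prior == "cauchy":
                lp += _cauchy_logpdf(beta[k], 3.0)
            else:
                lp += _normal_logpdf(beta[k], 3.0)
        return lp

    def _logpost(self, beta, u, log_tau, log_sigma):
        sigma = np.exp(log_sigma) if self.family == "gaussian" else 1.0
        tau = np.exp(log_tau)
        eta = self.X @ beta + u[self.groups]
        lp = float(np.sum(self._row_loglik(eta, sigma)))
        lp += self._beta_logprior(beta)
        lp += float(np.sum(_normal_logpdf(u, tau))) - self.J * log_tau
        lp += _t_logpdf(tau, 3.0, self.tau_scale) + log_tau  # half-t + jacobian
        if self.family == "gaussian":
            lp += _t_logpdf(sigma, 3.0, self.sigma_scale) + log_sigma
        return lp

    # --- initialisation -------------------------------------------------
    def _init_state(self, rng):
        import statsmodels.api as sm

        fam = sm.families.Gaussian() if self.family == "gaussian" else sm.families.Poisson()
        try:
            res = sm.GLM(self.y, self.X, family=fam).fit()
            beta0 = np.asarray(res.params, dtype=float)
            cov = np.asarray(res.cov_params(), dtype=float)
        except Exception:  # degenerate pooled fit; fall back to zeros
            beta0 = np.zeros(self.p)
            cov = np.eye(self.p)
        cov = cov + 1e-8 * np.eye(self.p)
        return beta0, cov

    # --- main loop ------------------------------------------------------
    def run(self, settings: SamplerSettings, seed: int) -> dict[str, np.ndarray]:
        """Sample; returns arrays of shape (chains, draws[, ...])."""
        beta_map, beta_cov = self._init_state(None)
        ss = np.random.SeedSequence(seed)
        out_beta = np.empty((settings.chains, settings.draws, self.p))
        out_tau = np.empty((settings.chains, settings.draws))
        out_sigma = np.empty((settings.chains, settings.draws))
        out_u = np.empty((settings.chains, settings.draws, self.J))
        for c, child in enumerate(ss.spawn(settings.chains)):
            rng = np.random.default_rng(child)
            if self.family == "gaussian":
                b, t, s, u = self._run_chain_gaussian(rng, settings, beta_map, beta_cov)
            else:
                b, t, s, u = self._run_chain(rng, settings, beta_map, beta_cov)
            out_beta[c], out_tau[c], out_sigma[c], out_u[c] = b, t, s, u
        res = {"beta": out_beta, "tau": out_tau, "u": out_u}
        if self.family == "gaussian":
            res["sigma"] = out_sigma
        return res

    # --- gaussian family: marginalized over u -------------------------
    def _gaussian_marginal_logpost(self, theta):
        """Log posterior of (beta, log tau, log sigma) with u integrated
        out; each group's covariance sigma^2 I + tau^2 11' is handled via
        Sherman-Morrison."""
        p = self.p
        beta = theta[:p]
        tau = np.exp(theta[p])
        sigma = np.exp(theta[p + 1])
        resid = self.y - self.X @ beta
        nj = self._nj
        s_j = np.bincount(self.groups, weights=resid, minlength=self.J)
        ssq_j = np.bincount(self.groups, weights=resid * resid, minlength=self.J)
        denom = sigma**2 + nj * tau**2
        quad = ssq_j / sigma**2 - (tau**2) * s_j**2 / (sigma**2 * denom)
        logdet = (nj - 1) * np.log(sigma**2) + np.log(denom)
        lp = -0.5 * float(np.sum(quad + logdet))
        lp += self._beta_logprior(beta)
        lp += _t_logpdf(tau, 3.0, self.tau_scale) + theta[p]  # half-t + jacobian
        lp += _t_logpdf(sigma, 3.0, self.sigma_scale) + theta[p + 1]
        return lp

    def _run_chain_gaussian(self, rng, settings, beta_map, beta_cov):
        p, J = self.p, self.J
        self._nj = np.bincount(self.groups, minlength=J).astype(float)
        dim = p + 2
        theta = np.empty(dim)
        theta[:p] = beta_map + rng.multivariate_normal(np.zeros(p), beta_cov)
        # moment-based variance split: within-group scatter -> sigma,
        # remaining between-group scatter -> tau
        resid0 = self.y - self.X @ beta_map
        gmean = np.bincount(self.groups, weights=resid0, minlength=J) / self._nj
        within = resid0 - gmean[self.groups]
        dof = max(float(np.sum(self._nj - 1)), 1.0)
        sig2 = max(float(np.sum(within**2)) / dof, 1e-6)
        tau2 = max(float(np.var(gmean)) - sig2 / float(np.mean(self._nj)), 0.05 * sig2)
        theta[p] = 0.5 * np.log(tau2) + 0.2 * rng.standard_normal()
        theta[p + 1] = 0.5 * np.log(sig2) + 0.2 * rng.standard_normal()

        cov0 = np.zeros((dim, dim))
        cov0[:p, :p] = beta_cov
        cov0[p, p] = cov0[p + 1, p + 1] = 0.05
        reg = 0.05 * np.diag(np.diag(cov0)) + 1e-10 * np.eye(dim)
        chol = np.linalg.cholesky(cov0 * (2.38**2 / dim) + 1e-10 * np.eye(dim))
        scale = 1.0

        n_iter = settings.warmup + settings.draws * settings.thin
        history = np.empty((settings.warmup, dim))
        keep_beta = np.empty((settings.draws, p))
        keep_tau = np.empty(settings.draws)
        keep_sigma = np.empty(settings.draws)
        keep_u = np.empty((settings.draws, J))
        kept = 0

        cur_lp = self._gaussian_marginal_logpost(theta)
        for it in range(n_iter):
            warm = it < settings.warmup
            prop = theta + scale * (chol @ rng.standard_normal(dim))
            prop_lp = self._gaussian_marginal_logpost(prop)
            accept = np.log(rng.random()) < prop_lp - cur_lp
            if accept:
                theta, cur_lp = prop, prop_lp
            if warm:
                history[it] = theta
                adapt = 0.6 / (1 + it) ** 0.6
                scale *= np.exp(adapt * ((1.0 if accept else 0.0) - 0.234))
                if it >= 200 and (it % 100 == 0 or it == settings.warmup - 1):
                    # regularise with a slice of the initial proposal so no
                    # coordinate's step collapses before it has ever moved
                    emp = np.atleast_2d(np.cov(history[it // 2 : it + 1].T)) + reg
                    chol = np.linalg.cholesky(emp * (2.38**2 / dim))
                    scale = 1.0
            if not warm and (it - settings.warmup) % settings.thin == 0:
                beta = theta[:p]
                tau, sigma = np.exp(theta[p]), np.exp(theta[p + 1])
                resid = self.y - self.X @ beta
                s_j = np.bincount(self.groups, weights=resid, minlength=J)
                v = 1.0 / (self._nj / sigma**2 + 1.0 / tau**2)
                keep_u[kept] = v * s_j / sigma**2 + np.sqrt(v) * rng.standard_normal(J)
                keep_beta[kept] = beta
                keep_tau[kept] = tau
                keep_sigma[kept] = sigma
                kept += 1
        return keep_beta, keep_tau, keep_sigma, keep_u

    def _run_chain(self, rng, settings, beta_map, beta_cov):
        p, J = self.p, self.J
        beta = beta_map + rng.multivariate_normal(np.zeros(p), beta_cov)
        u = rng.normal(0.0, 0.1, size=J)
        log_tau = np.log(0.5)
        log_sigma = 0.0  # unused for the poisson family
        sigma = 1.0

        chol = np.linalg.cholesky(beta_cov * (2.38**2 / p))
        beta_scale = 1.0
        u_scale = np.full(J, 0.5)
        tau_step, scale_step = 0.3, 0.3
        history = np.empty((settings.warmup, p))

        Xbeta = self.X @ beta
        gidx = self.groups

        def group_loglik(u_vec):
            eta = Xbeta + u_vec[gidx]
            return np.bincount(gidx, weights=self._row_loglik(eta, sigma), minlength=J)

        n_iter = settings.warmup + settings.draws * settings.thin
        keep_beta = np.empty((settings.draws, p))
        keep_tau = np.empty(settings.draws)
        keep_sigma = np.empty(settings.draws)
        keep_u = np.empty((settings.draws, J))
        kept = 0

        lik_rows = self._row_loglik(Xbeta + u[gidx], sigma)
        cur_lik = float(np.sum(lik_rows))

        for it in range(n_iter):
            warm = it < settings.warmup
            tau = np.exp(log_tau)

            # -- beta block
            prop = beta + beta_scale * (chol @ rng.standard_normal(p))
            Xb_prop = self.X @ prop
            lik_prop = float(np.sum(self._row_loglik(Xb_prop + u[gidx], sigma)))
            logr = (lik_prop + self._beta_logprior(prop)) - (cur_lik + self._beta_logprior(beta))
            accept = np.log(rng.random()) < logr
            if accept:
                beta, Xbeta, cur_lik = prop, Xb_prop, lik_prop
            if warm:
                history[it] = beta
                adapt = 0.6 / (1 + it) ** 0.6
                beta_scale *= np.exp(adapt * ((1.0 if accept else 0.0) - 0.234))
                if it >= 200 and it % 100 == 0:
                    emp = np.atleast_2d(np.cov(history[it // 2 : it + 1].T)) + 1e-9 * np.eye(p)
                    chol = np.linalg.cholesky(emp * (2.38**2 / p))
                    beta_scale = 1.0

            # -- u block (conditionally independent given beta)
            cur_g = group_loglik(u)
            u_prop = u + u_scale * rng.standard_normal(J)
            prop_g = group_loglik(u_prop)
            logr_u = (prop_g + _normal_logpdf(u_prop, tau)) - (
                cur_g + _normal_logpdf(u, tau)
            )
            acc_u = np.log(rng.random(J)) < logr_u
            u = np.where(acc_u, u_prop, u)
            if warm:
                adapt = 0.6 / (1 + it) ** 0.6
                u_scale *= np.exp(adapt * (np.where(acc_u, 1.0, 0.0) - 0.44))
                u_scale = np.clip(u_scale, 1e-3, 50.0)
            cur_lik = float(np.sum(np.where(acc_u, prop_g, cur_g)))

            # -- location swap: likelihood-invariant when an intercept exists
            if self.intercept_index is not None:
                d = rng.normal(0.0, tau / np.sqrt(J) + 1e-3)
                b0 = beta[self.intercept_index]
                logr_s = (
                    _t_logpdf(b0 + d - self.intercept_loc, 3.0, self.intercept_scale)
                    + np.sum(_normal_logpdf(u - d, tau))
                    - _t_logpdf(b0 - self.intercept_loc, 3.0, self.intercept_scale)
                    - np.sum(_normal_logpdf(u, tau))
                )
                if np.log(rng.random()) < logr_s:
                    beta = beta.copy()
                    beta[self.intercept_index] = b0 + d
                    u = u - d
                    Xbeta = self.X @ beta

            # -- scale interweave: (u, log tau) -> (a u, log tau + log a);
            #    moves along the variance funnel that the separate u / tau
            #    updates traverse slowly.  The N(u | 0, tau) exponent is
            #    invariant and its normalisation shift -J log a cancels the
            #    u-scaling jacobian +J log a exactly, leaving likelihood,
            #    half-t prior and the log-tau jacobian.
            eta_sc = scale_step * rng.standard_normal()
            a = np.exp(eta_sc)
            u_sc = u * a
            tau_sc = tau * a
            lik_sc = float(np.sum(self._row_loglik(Xbeta + u_sc[gidx], sigma)))
            logr_sc = (
                lik_sc
                - cur_lik
                + _t_logpdf(tau_sc, 3.0, self.tau_scale)
                - _t_logpdf(tau, 3.0, self.tau_scale)
                + eta_sc  # half-t jacobian (log-tau parameterisation)
            )
            acc_sc = np.log(rng.random()) < logr_sc
            if acc_sc:
                u = u_sc
                log_tau = log_tau + eta_sc
                tau = tau_sc
                cur_lik = lik_sc
            if warm:
                scale_step *= np.exp(
                    (0.6 / (1 + it) ** 0.6) * ((1.0 if acc_sc else 0.0) - 0.44)
                )
                scale_step = float(np.clip(scale_step, 1e-3, 2.0))

            # -- tau
            lt_prop = log_tau + tau_step * rng.standard_normal()
            t_prop = np.exp(lt_prop)
            logr_t = (
                np.sum(_normal_logpdf(u, t_prop)) - J * lt_prop
                + _t_logpdf(t_prop, 3.0, self.tau_scale) + lt_prop
            ) - (
                np.sum(_normal_logpdf(u, tau)) - J * log_tau
                + _t_logpdf(tau, 3.0, self.tau_scale) + log_tau
            )
            acc_t = np.log(rng.random()) < logr_t
            if acc_t:
                log_tau = lt_prop
            if warm:
                tau_step *= np.exp((0.6 / (1 + it) ** 0.6) * ((1.0 if acc_t else 0.0) - 0.44))

            if not warm and (it - settings.warmup) % settings.thin == 0:
                keep_beta[kept] = beta
                keep_tau[kept] = np.exp(log_tau)
                keep_sigma[kept] = np.exp(log_sigma)
                keep_u[kept] = u
                kept += 1

        return keep_beta, keep_tau, keep_sigma, keep_u
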