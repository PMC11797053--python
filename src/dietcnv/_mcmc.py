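"""Numba kernels for the phylogenetic GLMM sampler.

Metropolis-within-Gibbs for

    y_s ~ Poisson(exp(eta_s)),  eta_s = a + b x_s + u_s + e_s
    u ~ MVN(0, s2p * C),        e_s ~ N(0, s2e) iid

or, for the gaussian family,

    y_s ~ N(a + b x_s + u_s, s2e),   u ~ MVN(0, s2p * C).

Latent effects and fixed effects move by Gaussian random-walk proposals
(poisson family) or exact conjugate draws (gaussian family); both
variance components get conjugate inverse-gamma updates derived from the
univariate inverse-Wishart(V, nu) prior, i.e. IG(nu/2, nu*V/2).

Proposal step sizes adapt during burn-in toward 20-40% acceptance and are
frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TARGET_ACC = 0.3
_ADAPT_WINDOW = 50


@njit(cache=True)
def _inv_gamma(shape, scale):
    # X ~ Gamma(shape, 1/scale precision) => scale / Gamma(shape)
    return scale / np.random.gamma(shape, 1.0)


@njit(cache=True)
def poisson_chain(y, x, Cinv, V, nu, n_iter, burnin, thin, seed):
    """Run the Poisson-family chain; returns (draws, acc_rates).

    draws columns: a, b, s2p, s2e. Retained every ``thin`` iterations
    after ``burnin``.
    """
    np.random.seed(seed)
    n = y.shape[0]
    n_keep = (n_iter - burnin) // thin
    draws = np.empty((n_keep, 4))

    a = np.log(y.mean() + 0.5)
    b = 0.0
    u = np.zeros(n)
    e = np.zeros(n)
    s2p = 0.1
    s2e = 0.1
    g = np.zeros(n)  # Cinv @ u, maintained incrementally
    eta = a + b * x + u + e
    # precomputations for likelihood-invariant translation moves
    Cx = Cinv @ x
    C1 = Cinv @ np.ones(n)
    xCx = x @ Cx
    oneC1 = np.ones(n) @ C1

    step_u = 0.5
    step_e = 0.5
    step_a = 0.2
    step_b = 0.2
    step_t = 0.5
    acc_u = 0.0
    acc_e = 0.0
    acc_a = 0.0
    acc_b = 0.0
    acc_t = 0.0
    n_u = 0.0
    n_s = 0.0
    n_t = 0.0

    kept = 0
    for it in range(n_iter):
        # --- latent phylogenetic effects u, componentwise MH
        for s in range(n):
            d = step_u * np.random.normal()
            dlp = -(2.0 * d * g[s] + d * d * Cinv[s, s]) / (2.0 * s2p)
            dll = y[s] * d - np.exp(eta[s] + d) + np.exp(eta[s])
            if np.log(np.random.random()) < dlp + dll:
                u[s] += d
                eta[s] += d
                for t in range(n):
                    g[t] += d * Cinv[t, s]
                acc_u += 1.0
            n_u += 1.0
        # --- iid residual effects e
        for s in range(n):
            d = step_e * np.random.normal()
            dlp = -(2.0 * d * e[s] + d * d) / (2.0 * s2e)
            dll = y[s] * d - np.exp(eta[s] + d) + np.exp(eta[s])
            if np.log(np.random.random()) < dlp + dll:
                e[s] += d
                eta[s] += d
                acc_e += 1.0
            n_u += 1.0
        # --- intercept a (flat prior)
        d = step_a * np.random.normal()
        dll = 0.0
        for s in range(n):
            dll += y[s] * d - np.exp(eta[s] + d) + np.exp(eta[s])
        if np.log(np.random.random()) < dll:
            a += d
            eta += d
            acc_a += 1.0
        n_s += 1.0
        # --- slope b (flat prior)
        d = step_b * np.random.normal()
        dll = 0.0
        for s in range(n):
            dll += y[s] * d * x[s] - np.exp(eta[s] + d * x[s]) + np.exp(eta[s])
        if np.log(np.random.random()) < dll:
            b += d
            eta = eta + d * x
            acc_b += 1.0
        # --- likelihood-invariant translations along confounded directions:
        # shift a fixed effect and absorb it in the latent effects so eta
        # (hence the likelihood) is unchanged; accepted on the prior ratio.
        # These decorrelate (a, u), (b, u), (a, e), (b, e).
        d = step_t * np.random.normal()  # b' = b + d, u' = u - d x
        dlp = -(-2.0 * d * (x @ g) + d * d * xCx) / (2.0 * s2p)
        if np.log(np.random.random()) < dlp:
            b += d
            u -= d * x
            g -= d * Cx
            acc_t += 1.0
        d = step_t * np.random.normal()  # a' = a + d, u' = u - d
        dlp = -(-2.0 * d * g.sum() + d * d * oneC1) / (2.0 * s2p)
        if np.log(np.random.random()) < dlp:
            a += d
            u -= d
            g -= d * C1
            acc_t += 1.0
        d = step_t * np.random.normal()  # b' = b + d, e' = e - d x
        dlp = -(-2.0 * d * (x @ e) + d * d * (x @ x)) / (2.0 * s2e)
        if np.log(np.random.random()) < dlp:
            b += d
            e -= d * x
            acc_t += 1.0
        d = step_t * np.random.normal()  # a' = a + d, e' = e - d
        dlp = -(-2.0 * d * e.sum() + d * d * n) / (2.0 * s2e)
        if np.log(np.random.random()) < dlp:
            a += d
            e -= d
            acc_t += 1.0
        n_t += 4.0
        # --- conjugate variance updates
        quad = 0.0
        for s in range(n):
            quad += u[s] * g[s]
        s2p = _inv_gamma((nu + n) / 2.0, (nu * V + quad) / 2.0)
        sse = 0.0
        for s in range(n):
            sse += e[s] * e[s]
        s2e = _inv_gamma((nu + n) / 2.0, (nu * V + sse) / 2.0)

        if not np.isfinite(eta).all():
            raise FloatingPointError("divergent chain: non-finite eta")

        # --- burn-in step-size adaptation
        if it < burnin and (it + 1) % _ADAPT_WINDOW == 0:
            if acc_u / max(n_u / 2.0, 1.0) > _TARGET_ACC:
                step_u *= 1.1
            else:
                step_u *= 0.9
            if acc_e / max(n_u / 2.0, 1.0) > _TARGET_ACC:
                step_e *= 1.1
            else:
                step_e *= 0.9
            if acc_a / n_s > _TARGET_ACC:
                step_a *= 1.1
            else:
                step_a *= 0.9
            if acc_b / n_s > _TARGET_ACC:
                step_b *= 1.1
            else:
                step_b *= 0.9
            if acc_t / n_t > _TARGET_ACC:
                step_t *= 1.1
            else:
                step_t *= 0.9
            acc_u = acc_e = acc_a = acc_b = acc_t = 0.0
            n_u = 0.0
            n_s = 0.0
            n_t = 0.0

        if it >= burnin and (it - burnin) % thin == thin - 1:
            draws[kept, 0] = a
            draws[kept, 1] = b
            draws[kept, 2] = s2p
            draws[kept, 3] = s2e
            kept += 1

    rates = np.empty(4)
    rates[0] = acc_a / max(n_s, 1.0)
    rates[1] = acc_b / max(n_s, 1.0)
    rates[2] = acc_u / max(n_u / 2.0, 1.0)
    rates[3] = acc_e / max(n_u / 2.0, 1.0)
    return draws[:kept], rates


@njit(cache=True)
def gaussian_chain(y, x, Cinv, V, nu, n_iter, burnin, thin, seed):
    """Gaussian-family chain: exact Gibbs throughout."""
    np.random.seed(seed)
    n = y.shape[0]
    n_keep = (n_iter - burnin) // thin
    draws = np.empty((n_keep, 4))

    a = y.mean()
    b = 0.0
    u = np.zeros(n)
    s2p = 0.1
    s2e = max(y.var(), 1e-6)

    kept = 0
    for it in range(n_iter):
        # u | rest ~ MVN(P^-1 r / s2e, P^-1), P = Cinv/s2p + I/s2e
        P = Cinv / s2p
        for s in range(n):
            P[s, s] += 1.0 / s2e
        L = np.linalg.cholesky(P)
        r = (y - a - b * x) / s2e
        # solve P m = r via Cholesky
        z = np.linalg.solve(L, r)
        m = np.linalg.solve(L.T, z)
        w = np.random.normal(0.0, 1.0, n)
        u = m + np.linalg.solve(L.T, w)
        # (a, b) | rest: OLS of (y - u) on [1 x], flat prior
        res = y - u
        sx = x.sum()
        sxx = (x * x).sum()
        det = n * sxx - sx * sx
        ahat = (sxx * res.sum() - sx * (x * res).sum()) / det
        bhat = (n * (x * res).sum() - sx * res.sum()) / det
        # covariance s2e * inv([[n, sx],[sx, sxx]])
        c11 = s2e * sxx / det
        c22 = s2e * n / det
        c12 = -s2e * sx / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(max(c22 - l21 * l21, 1e-300))
        z1 = np.random.normal()
        z2 = np.random.normal()
        a = ahat + l11 * z1
        b = bhat + l21 * z1 + l22 * z2
        # variances
        gq = u @ (Cinv @ u)
        s2p = _inv_gamma((nu + n) / 2.0, (nu * V + gq) / 2.0)
        resid = y - a - b * x - u
        s2e = _inv_gamma((nu + n) / 2.0, (nu * V + (resid * resid).sum()) / 2.0)

        if it >= burnin and (it - burnin) % thin == thin - 1:
            draws[kept, 0] = a
            draws[kept, 1] = b
            draws[kept, 2] = s2p
            draws[kept, 3] = s2e
            kept += 1

    rates = np.ones(4)
    return draws[:kept], rates
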