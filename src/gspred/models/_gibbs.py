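"""Compiled single-site Gibbs sweeps for marker-effect models.

The samplers walk markers in fixed order keeping a running residual
vector, so one update costs O(n).  Chains are driven by numba's
numpy-compatible RNG seeded once per call, which makes them bit-identical
for a given seed on a given numba version.

Variant codes: 0 = ridge (RR-BLUP, all markers in), 1 = BayesB
(spike-and-slab, marker-specific slab variances), 2 = BayesC
(spike-and-slab, one shared slab variance).
"""

from __future__ import annotations

import numpy as np
from numba import njit

VARIANT_RR = 0
VARIANT_BAYESB = 1
VARIANT_BAYESC = 2


@njit(cache=True)
def marker_chain(
    y,
    W,
    variant,
    pi,
    nu,
    S_alpha,
    S_e,
    n_iter,
    burn_in,
    thin,
    seed,
    fix_s2e,
    s2e_fixed,
    fix_s2a,
    s2a_fixed,
):
    """Gibbs chain for y = 1 mu + W alpha + eps with spike-and-slab priors.

    Returns (mu_chain, s2e_chain, s2a_chain, genvar_chain, alpha_mean,
    incl_prob, alpha_chain).  ``s2a_chain`` is the shared slab variance for
    ridge/BayesC and the mean of the marker-specific variances for BayesB;
    ``genvar_chain`` is var(W @ alpha) per saved draw.
    """
    np.random.seed(seed)
    n, m = W.shape
    n_saved = (n_iter - burn_in + thin - 1) // thin

    c = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        c[j] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    if variant == VARIANT_RR:
        delta[:] = 1
    s2a_j = np.full(m, S_alpha / (nu + 2.0))
    s2a = S_alpha / (nu + 2.0) if not fix_s2a else s2a_fixed
    if fix_s2a:
        s2a_j[:] = s2a_fixed
    s2e = S_e / (nu + 2.0) if not fix_s2e else s2e_fixed

    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - mu

    mu_chain = np.empty(n_saved)
    s2e_chain = np.empty(n_saved)
    s2a_chain = np.empty(n_saved)
    genvar_chain = np.empty(n_saved)
    alpha_mean = np.zeros(m)
    incl_sum = np.zeros(m)
    alpha_chain = np.empty((n_saved, m))

    s = 0
    for it in range(n_iter):
        # intercept
        rbar = 0.0
        for i in range(n):
            rbar += r[i] + mu
        rbar /= n
        mu_new = np.random.normal(rbar, np.sqrt(s2e / n))
        dmu = mu - mu_new
        for i in range(n):
            r[i] += dmu
        mu = mu_new

        # marker sweep
        for j in range(m):
            if c[j] == 0.0:
                alpha[j] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * r[i]
            rhs += c[j] * alpha[j]
            old = alpha[j]
            if variant == VARIANT_RR:
                v = c[j] + s2e / s2a
                new = np.random.normal(rhs / v, np.sqrt(s2e / v))
                delta[j] = 1
            else:
                sj = s2a_j[j] if variant == VARIANT_BAYESB else s2a
                denom = s2e + c[j] * sj
                log_bf = 0.5 * (np.log(s2e / denom) + rhs * rhs * sj / (s2e * denom))
                log_odds = np.log((1.0 - pi) / pi) + log_bf
                if log_odds > 35.0:
                    p_incl = 1.0
                elif log_odds < -35.0:
                    p_incl = 0.0
                else:
                    p_incl = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_incl:
                    v = c[j] + s2e / sj
                    new = np.random.normal(rhs / v, np.sqrt(s2e / v))
                    delta[j] = 1
                else:
                    new = 0.0
                    delta[j] = 0
            if new != old:
                d = old - new
                for i in range(n):
                    r[i] += W[i, j] * d
                alpha[j] = new

        # slab variances
        if not fix_s2a:
            if variant == VARIANT_BAYESB:
                for j in range(m):
                    if delta[j] == 1:
                        s2a_j[j] = (S_alpha + alpha[j] * alpha[j]) / np.random.chisquare(
                            nu + 1.0
                        )
                    else:
                        s2a_j[j] = S_alpha / np.random.chisquare(nu)
            else:
                ss = 0.0
                k = 0
                for j in range(m):
                    if delta[j] == 1:
                        ss += alpha[j] * alpha[j]
                        k += 1
                s2a = (S_alpha + ss) / np.random.chisquare(nu + k)

        # residual variance
        if not fix_s2e:
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            s2e = (S_e + rss) / np.random.chisquare(nu + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_chain[s] = mu
            s2e_chain[s] = s2e
            if variant == VARIANT_BAYESB:
                s2a_chain[s] = s2a_j.mean()
            else:
                s2a_chain[s] = s2a
            g_mean = 0.0
            g_sq = 0.0
            for i in range(n):
                gi = y[i] - mu - r[i]
                g_mean += gi
                g_sq += gi * gi
            g_mean /= n
            genvar_chain[s] = g_sq / n - g_mean * g_mean
            for j in range(m):
                alpha_mean[j] += alpha[j]
                incl_sum[j] += delta[j]
                alpha_chain[s, j] = alpha[j]
            s += 1

    for j in range(m):
        alpha_mean[j] /= n_saved
        incl_sum[j] /= n_saved
    return mu_chain, s2e_chain, s2a_chain, genvar_chain, alpha_mean, incl_sum, alpha_chain


@njit(cache=True)
def mxe_chain(
    y_stack,
    W_stack,
    env_start,
    nu,
    S_alpha0,
    S_alpha_l,
    S_e_l,
    n_iter,
    burn_in,
    thin,
    seed,
    fix_specific,
    specific_fixed,
    fix_resid,
    resid_fixed,
):
    """Gibbs chain for the marker-by-environment interaction model.

    y_il = mu_l + sum_k w_ilk (alpha0_k + alpha_lk) + eps_il with
    heterogeneous residual variances.  ``y_stack``/``W_stack`` hold the
    observed records of all environments stacked; ``env_start`` (length
    L + 1) delimits each environment's rows.

    Returns (mu_chain, s2a0_chain, s2al_chain, s2el_chain, alpha0_mean,
    alphal_mean).
    """
    np.random.seed(seed)
    L = env_start.size - 1
    m = W_stack.shape[1]
    n_saved = (n_iter - burn_in + thin - 1) // thin

    c = np.zeros((L, m))
    for l in range(L):
        for i in range(env_start[l], env_start[l + 1]):
            for j in range(m):
                c[l, j] += W_stack[i, j] * W_stack[i, j]

    mu = np.zeros(L)
    for l in range(L):
        n_l = env_start[l + 1] - env_start[l]
        s = 0.0
        for i in range(env_start[l], env_start[l + 1]):
            s += y_stack[i]
        mu[l] = s / n_l

    alpha0 = np.zeros(m)
    alphal = np.zeros((L, m))
    s2a0 = S_alpha0 / (nu + 2.0)
    s2al = np.empty(L)
    s2el = np.empty(L)
    for l in range(L):
        s2al[l] = specific_fixed[l] if fix_specific else S_alpha_l[l] / (nu + 2.0)
        s2el[l] = resid_fixed[l] if fix_resid else S_e_l[l] / (nu + 2.0)

    r = np.empty(y_stack.size)
    for l in range(L):
        for i in range(env_start[l], env_start[l + 1]):
            r[i] = y_stack[i] - mu[l]

    mu_chain = np.empty((n_saved, L))
    s2a0_chain = np.empty(n_saved)
    s2al_chain = np.empty((n_saved, L))
    s2el_chain = np.empty((n_saved, L))
    alpha0_mean = np.zeros(m)
    alphal_mean = np.zeros((L, m))

    s = 0
    for it in range(n_iter):
        # environment intercepts
        for l in range(L):
            n_l = env_start[l + 1] - env_start[l]
            rbar = 0.0
            for i in range(env_start[l], env_start[l + 1]):
                rbar += r[i] + mu[l]
            rbar /= n_l
            mu_new = np.random.normal(rbar, np.sqrt(s2el[l] / n_l))
            dmu = mu[l] - mu_new
            for i in range(env_start[l], env_start[l + 1]):
                r[i] += dmu
            mu[l] = mu_new

        # main marker effects (precision-weighted across environments)
        for j in range(m):
            v = 1.0 / s2a0
            rhs = 0.0
            for l in range(L):
                if c[l, j] == 0.0:
                    continue
                wr = 0.0
                for i in range(env_start[l], env_start[l + 1]):
                    wr += W_stack[i, j] * r[i]
                rhs += (wr + c[l, j] * alpha0[j]) / s2el[l]
                v += c[l, j] / s2el[l]
            new = np.random.normal(rhs / v, np.sqrt(1.0 / v))
            d = alpha0[j] - new
            if d != 0.0:
                for i in range(y_stack.size):
                    r[i] += W_stack[i, j] * d
                alpha0[j] = new

        # environment-specific marker effects
        for l in range(L):
            for j in range(m):
                if c[l, j] == 0.0:
                    alphal[l, j] = 0.0
                    continue
                wr = 0.0
                for i in range(env_start[l], env_start[l + 1]):
                    wr += W_stack[i, j] * r[i]
                rhs = (wr + c[l, j] * alphal[l, j]) / s2el[l]
                v = c[l, j] / s2el[l] + 1.0 / s2al[l]
                new = np.random.normal(rhs / v, np.sqrt(1.0 / v))
                d = alphal[l, j] - new
                if d != 0.0:
                    for i in range(env_start[l], env_start[l + 1]):
                        r[i] += W_stack[i, j] * d
                    alphal[l, j] = new

        # variance components
        ss0 = 0.0
        for j in range(m):
            ss0 += alpha0[j] * alpha0[j]
        s2a0 = (S_alpha0 + ss0) / np.random.chisquare(nu + m)
        if not fix_specific:
            for l in range(L):
                ssl = 0.0
                for j in range(m):
                    ssl += alphal[l, j] * alphal[l, j]
                s2al[l] = (S_alpha_l[l] + ssl) / np.random.chisquare(nu + m)
        if not fix_resid:
            for l in range(L):
                rss = 0.0
                n_l = env_start[l + 1] - env_start[l]
                for i in range(env_start[l], env_start[l + 1]):
                    rss += r[i] * r[i]
                s2el[l] = (S_e_l[l] + rss) / np.random.chisquare(nu + n_l)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for l in range(L):
                mu_chain[s, l] = mu[l]
                s2al_chain[s, l] = s2al[l]
                s2el_chain[s, l] = s2el[l]
            s2a0_chain[s] = s2a0
            for j in range(m):
                alpha0_mean[j] += alpha0[j]
                for l in range(L):
                    alphal_mean[l, j] += alphal[l, j]
            s += 1

    for j in range(m):
        alpha0_mean[j] /= n_saved
        for l in range(L):
            alphal_mean[l, j] /= n_saved
    return mu_chain, s2a0_chain, s2al_chain, s2el_chain, alpha0_mean, alphal_mean
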