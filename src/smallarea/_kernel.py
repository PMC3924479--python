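"""Numba kernel: single-site adaptive random-walk Metropolis-within-Gibbs.

One call runs one chain of the Poisson BYM-type model

    O_i ~ Poisson(E_i * exp(alpha + X_i beta + S_i + H_i))

with a flat prior on alpha, N(0, prior_beta_var) on each beta_k, the
intrinsic CAR on S (conditional N(neighbor mean, sigma_S^2 / n_i), improper
density with normalization sigma_S^{-(n-c)}), i.i.d. N(0, sigma_H^2) on H,
and independent U(0, sigma_upper) priors on sigma_S and sigma_H.

Updates per sweep: alpha; each beta_k; each S_i (then per-component
recentering of S with the grand mean absorbed into alpha); each H_i;
sigma_H and sigma_S by random-walk MH on their conditionals.  Proposal
standard deviations are log-adapted toward ``target_accept`` during
burn-in only, so the post-burn-in kernel is a fixed Markov kernel.

The expensive state (eta_i = log lambda_i and mu_i = E_i exp(eta_i)) is
maintained incrementally.  ``use_like`` = False switches the likelihood
off for prior-only sampling; in that mode alpha (whose flat prior is
improper, hence not samplable) is held fixed and the stored log likelihood
is NaN.
"""

import math

import numpy as np
from numba import njit

# slot order of the per-block acceptance statistics returned by run_chain:
# 0: alpha, 1: beta (pooled), 2: S (pooled), 3: H (pooled), 4: sigma_S, 5: sigma_H
N_BLOCKS = 6


@njit(cache=True)
def _poisson_loglik(O, mu, logfact):
    out = 0.0
    for i in range(O.shape[0]):
        out += O[i] * math.log(mu[i]) - mu[i] - logfact[i]
    return out


@njit(cache=True)
def run_chain(O, E, X, logfact,
              indptr, indices, comp_id, comp_count, n_comp,
              include_spatial, include_het, use_like,
              prior_beta_var, sigma_upper,
              n_iter, burn_in, thin, target_accept, adapt_interval,
              alpha0, beta0, S0, H0, sig_s0, sig_h0, seed):
    np.random.seed(seed)
    n = O.shape[0]
    p = X.shape[1]
    rank_S = n - n_comp

    alpha = alpha0
    beta = beta0.copy()
    S = S0.copy()
    H = H0.copy()
    sig_s = sig_s0
    sig_h = sig_h0

    eta = np.empty(n)
    mu = np.empty(n)
    for i in range(n):
        v = alpha + S[i] + H[i]
        for k in range(p):
            v += X[i, k] * beta[k]
        eta[i] = v
        mu[i] = E[i] * math.exp(v)

    # log proposal scales
    ls_alpha = math.log(0.1)
    ls_beta = np.full(p, math.log(0.1))
    ls_S = math.log(0.5)
    ls_H = math.log(0.5)
    ls_ss = math.log(0.1)
    ls_sh = math.log(0.1)

    # one adaptive scale per update family: alpha, each beta_k, S, H, sigmas
    n_scales = 1 + p + 4
    win_acc = np.zeros(n_scales)
    win_try = np.zeros(n_scales)
    post_acc = np.zeros(N_BLOCKS)
    post_try = np.zeros(N_BLOCKS)

    n_keep = (n_iter - burn_in) // thin
    alpha_d = np.empty(n_keep)
    beta_d = np.empty((n_keep, p))
    S_d = np.empty((n_keep, n))
    H_d = np.empty((n_keep, n))
    sig_s_d = np.empty(n_keep)
    sig_h_d = np.empty(n_keep)
    ll_d = np.empty(n_keep)

    kept = 0
    n_window = 0
    for it in range(n_iter):
        in_burn = it < burn_in

        # ---- alpha (flat prior; fixed in prior-only mode) ----
        if use_like:
            d = math.exp(ls_alpha) * np.random.normal()
            fac = math.exp(d)
            dlp = 0.0
            for i in range(n):
                dlp += O[i] * d - mu[i] * (fac - 1.0)
            win_try[0] += 1.0
            if not in_burn:
                post_try[0] += 1.0
            if math.log(np.random.random()) < dlp:
                alpha += d
                for i in range(n):
                    eta[i] += d
                    mu[i] *= fac
                win_acc[0] += 1.0
                if not in_burn:
                    post_acc[0] += 1.0

        # ---- beta ----
        for k in range(p):
            d = math.exp(ls_beta[k]) * np.random.normal()
            bnew = beta[k] + d
            dlp = -(bnew * bnew - beta[k] * beta[k]) / (2.0 * prior_beta_var)
            if use_like:
                for i in range(n):
                    de = d * X[i, k]
                    dlp += O[i] * de - mu[i] * (math.exp(de) - 1.0)
            win_try[1 + k] += 1.0
            if not in_burn:
                post_try[1] += 1.0
            if math.log(np.random.random()) < dlp:
                beta[k] = bnew
                if use_like:
                    for i in range(n):
                        de = d * X[i, k]
                        eta[i] += de
                        mu[i] *= math.exp(de)
                win_acc[1 + k] += 1.0
                if not in_burn:
                    post_acc[1] += 1.0

        # ---- S (intrinsic CAR), then per-component recentering ----
        if include_spatial:
            step = math.exp(ls_S)
            inv2ss = 1.0 / (2.0 * sig_s * sig_s)
            for i in range(n):
                ni = indptr[i + 1] - indptr[i]
                if ni == 0:
                    continue  # island pinned at its current (zero) value
                nbsum = 0.0
                for jj in range(indptr[i], indptr[i + 1]):
                    nbsum += S[indices[jj]]
                nbmean = nbsum / ni
                d = step * np.random.normal()
                snew = S[i] + d
                dlp = -ni * inv2ss * ((snew - nbmean) ** 2 - (S[i] - nbmean) ** 2)
                if use_like:
                    dlp += O[i] * d - mu[i] * (math.exp(d) - 1.0)
                win_try[1 + p] += 1.0
                if not in_burn:
                    post_try[2] += 1.0
                if math.log(np.random.random()) < dlp:
                    S[i] = snew
                    if use_like:
                        eta[i] += d
                        mu[i] *= math.exp(d)
                    win_acc[1 + p] += 1.0
                    if not in_burn:
                        post_acc[2] += 1.0
            # recenter: subtract each component's mean, absorb grand mean in alpha
            cmean = np.zeros(n_comp)
            for i in range(n):
                cmean[comp_id[i]] += S[i]
            gmean = 0.0
            for c in range(n_comp):
                gmean += cmean[c]
                cmean[c] /= comp_count[c]
            gmean /= n
            alpha += gmean
            for i in range(n):
                shift = gmean - cmean[comp_id[i]]
                S[i] -= cmean[comp_id[i]]
                if use_like and shift != 0.0:
                    eta[i] += shift
                    mu[i] *= math.exp(shift)

        # ---- H (exchangeable heterogeneity) ----
        if include_het:
            step = math.exp(ls_H)
            inv2sh = 1.0 / (2.0 * sig_h * sig_h)
            for i in range(n):
                d = step * np.random.normal()
                hnew = H[i] + d
                dlp = -(hnew * hnew - H[i] * H[i]) * inv2sh
                if use_like:
                    dlp += O[i] * d - mu[i] * (math.exp(d) - 1.0)
                win_try[2 + p] += 1.0
                if not in_burn:
                    post_try[3] += 1.0
                if math.log(np.random.random()) < dlp:
                    H[i] = hnew
                    if use_like:
                        eta[i] += d
                        mu[i] *= math.exp(d)
                    win_acc[2 + p] += 1.0
                    if not in_burn:
                        post_acc[3] += 1.0

        # ---- sigma_S | S : dens prop to sig^-(n-c) exp(-q/(2 sig^2)) on (0,U)
        if include_spatial:
            qform = 0.0
            for i in range(n):
                for jj in range(indptr[i], indptr[i + 1]):
                    j = indices[jj]
                    if j > i:
                        qform += (S[i] - S[j]) ** 2
            prop = sig_s + math.exp(ls_ss) * np.random.normal()
            win_try[3 + p] += 1.0
            if not in_burn:
                post_try[4] += 1.0
            if 0.0 < prop < sigma_upper:
                dlp = (-rank_S * (math.log(prop) - math.log(sig_s))
                       - 0.5 * qform * (1.0 / (prop * prop) - 1.0 / (sig_s * sig_s)))
                if math.log(np.random.random()) < dlp:
                    sig_s = prop
                    win_acc[3 + p] += 1.0
                    if not in_burn:
                        post_acc[4] += 1.0

        # ---- sigma_H | H ----
        if include_het:
            ssq = 0.0
            for i in range(n):
                ssq += H[i] * H[i]
            prop = sig_h + math.exp(ls_sh) * np.random.normal()
            win_try[4 + p] += 1.0
            if not in_burn:
                post_try[5] += 1.0
            if 0.0 < prop < sigma_upper:
                dlp = (-n * (math.log(prop) - math.log(sig_h))
                       - 0.5 * ssq * (1.0 / (prop * prop) - 1.0 / (sig_h * sig_h)))
                if math.log(np.random.random()) < dlp:
                    sig_h = prop
                    win_acc[4 + p] += 1.0
                    if not in_burn:
                        post_acc[5] += 1.0

        # ---- adapt proposal scales (burn-in only) ----
        if in_burn and (it + 1) % adapt_interval == 0:
            n_window += 1
            gain = 2.0 / math.sqrt(n_window) if n_window > 16 else 0.5
            for s in range(n_scales):
                if win_try[s] > 0.0:
                    delta = gain * (win_acc[s] / win_try[s] - target_accept)
                    if s == 0:
                        ls_alpha += delta
                    elif s <= p:
                        ls_beta[s - 1] += delta
                    elif s == 1 + p:
                        ls_S += delta
                    elif s == 2 + p:
                        ls_H += delta
                    elif s == 3 + p:
                        ls_ss += delta
                    else:
                        ls_sh += delta
                win_acc[s] = 0.0
                win_try[s] = 0.0

        # ---- store ----
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            alpha_d[kept] = alpha
            for k in range(p):
                beta_d[kept, k] = beta[k]
            for i in range(n):
                S_d[kept, i] = S[i]
                H_d[kept, i] = H[i]
            sig_s_d[kept] = sig_s
            sig_h_d[kept] = sig_h
            ll_d[kept] = _poisson_loglik(O, mu, logfact) if use_like else np.nan
            kept += 1

    acc_rate = np.full(N_BLOCKS, np.nan)
    for b in range(N_BLOCKS):
        if post_try[b] > 0.0:
            acc_rate[b] = post_acc[b] / post_try[b]
    return alpha_d, beta_d, S_d, H_d, sig_s_d, sig_h_d, ll_d, acc_rate
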