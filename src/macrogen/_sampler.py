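"""Numba-compiled MCMC kernel shared by both model families.

The posterior is explored with adaptive random-walk Metropolis-within-Gibbs:
scalar updates for fixed effects, dispersion coefficients, species effects
(restricted likelihood rows per species) and region effects (restricted rows
per region), a joint recentring move that shifts the region effects' mean
into the intercept (likelihood- and CAR-prior-invariant, Metropolis-corrected
for the intercept prior), a scalar update for the species-effect scale, and
a conjugate Gibbs draw for the CAR precision.  Proposal scales adapt toward
44% acceptance during burn-in and are frozen afterwards, so chains are valid
Markov chains post burn-in and fully deterministic given the seed.

Likelihood kinds: 0 = beta regression (logit-mean, log-dispersion in n),
1 = Gaussian (identity link, log-sd in n).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_SQRT_2PI = 0.9189385332046727


@njit(cache=True)
def _loglik_full(kind, eta, disp, lgd, y, ly, l1y):
    """Total log-likelihood. disp: delta (beta) or log-sigma (gaussian)."""
    ll = 0.0
    if kind == 0:
        for i in range(eta.size):
            mu = 1.0 / (1.0 + math.exp(-eta[i]))
            a = mu * disp[i]
            b = disp[i] - a
            if a <= 0.0 or b <= 0.0 or not math.isfinite(a):
                return -np.inf
            ll += lgd[i] - math.lgamma(a) - math.lgamma(b) \
                + (a - 1.0) * ly[i] + (b - 1.0) * l1y[i]
    else:
        for i in range(eta.size):
            r = (y[i] - eta[i]) * math.exp(-disp[i])
            ll += -LOG_SQRT_2PI - disp[i] - 0.5 * r * r
    return ll


@njit(cache=True)
def _loglik_rows(kind, eta, disp, lgd, y, ly, l1y, rows, lo, hi):
    ll = 0.0
    if kind == 0:
        for t in range(lo, hi):
            i = rows[t]
            mu = 1.0 / (1.0 + math.exp(-eta[i]))
            a = mu * disp[i]
            b = disp[i] - a
            if a <= 0.0 or b <= 0.0 or not math.isfinite(a):
                return -np.inf
            ll += lgd[i] - math.lgamma(a) - math.lgamma(b) \
                + (a - 1.0) * ly[i] + (b - 1.0) * l1y[i]
    else:
        for t in range(lo, hi):
            i = rows[t]
            r = (y[i] - eta[i]) * math.exp(-disp[i])
            ll += -LOG_SQRT_2PI - disp[i] - 0.5 * r * r
    return ll


@njit(cache=True)
def _set_disp(kind, g0, g1, logn, disp, lgd):
    """Fill dispersion arrays from the (g0, g1) sub-model; False if invalid."""
    if kind == 0:
        for i in range(logn.size):
            d = math.exp(g0 + g1 * logn[i])
            if d <= 0.0 or d > 1e12 or not math.isfinite(d):
                return False
            disp[i] = d
            lgd[i] = math.lgamma(d)
    else:
        for i in range(logn.size):
            disp[i] = g0 + g1 * logn[i]
    return True


@njit(cache=True)
def run_chain(
    kind,
    y, ly, l1y, X, logn,
    sp_rows, sp_ptr, reg_rows, reg_ptr,
    Pm, Q0, car_rank, include_region,
    n_iter, burnin, thin, seed,
    beta_sd, g_sd, sigs_scale, taur_shape, taur_rate,
    beta0_init, g0_init,
    lat_col, lat2_col, regc1, regc2,
):
    np.random.seed(seed)
    n, p = X.shape
    ns = sp_ptr.size - 1
    nr = reg_ptr.size - 1 if include_region else 0

    # overdispersed start: jitter all blocks so chains begin apart and the
    # between-chain R-hat can see slow directions
    beta = np.zeros(p)
    beta[0] = beta0_init
    for j in range(p):
        beta[j] += 0.3 * np.random.normal()
    S = 0.3 * np.random.standard_normal(ns)
    R = 0.2 * np.random.standard_normal(nr)
    if nr > 0:
        R -= R.sum() / nr
    g0 = g0_init + 0.2 * np.random.normal()
    g1 = 0.1 * np.random.normal()
    lsigS = math.log(0.5) + 0.3 * np.random.normal()
    tauR = 10.0

    # eta = X beta + S[sp] + R[reg]; build from the row-group arrays
    eta = X @ beta
    for js in range(ns):
        for t in range(sp_ptr[js], sp_ptr[js + 1]):
            eta[sp_rows[t]] += S[js]
    if include_region:
        for jr in range(nr):
            for t in range(reg_ptr[jr], reg_ptr[jr + 1]):
                eta[reg_rows[t]] += R[jr]
    disp = np.zeros(n)
    lgd = np.zeros(n)
    _set_disp(kind, g0, g1, logn, disp, lgd)
    ll = _loglik_full(kind, eta, disp, lgd, y, ly, l1y)
    if not math.isfinite(ll):  # fall back to a flat start
        for j in range(p):
            beta[j] = 0.0
        beta[0] = beta0_init
        S[:] = 0.0
        R[:] = 0.0
        g0, g1 = g0_init, 0.0
        eta = X @ beta
        _set_disp(kind, g0, g1, logn, disp, lgd)
        ll = _loglik_full(kind, eta, disp, lgd, y, ly, l1y)

    # n scalar adaptive steps: p betas, 2 dispersion, ns species, nr regions,
    # 1 sigma_S, 1 species-mean shift, 2 region-pattern ridge moves
    n_scalar = p + 2 + ns + nr + 1 + 3
    lstep = np.full(n_scalar, math.log(0.2))
    adapt = 0.08

    n_keep = (n_iter - burnin) // thin
    P = p + ns + nr + 4  # + g0, g1, sigma_S, tau_R
    out = np.zeros((n_keep, P))
    out_ll = np.zeros(n_keep)
    kept = 0

    Pm_colsum = np.zeros(ns)
    for a in range(ns):
        for b in range(ns):
            Pm_colsum[b] += Pm[a, b]
    Pm_total = Pm_colsum.sum()

    quadS = 0.0  # S' Pm S, maintained incrementally
    for a in range(ns):
        rowdot = 0.0
        for b in range(ns):
            rowdot += Pm[a, b] * S[b]
        quadS += S[a] * rowdot
    for it in range(n_iter):
        adapting = it < burnin
        # --- fixed effects ---
        for j in range(p):
            st = math.exp(lstep[j])
            dz = st * np.random.normal()
            eta_new = eta + X[:, j] * dz
            ll_new = _loglik_full(kind, eta_new, disp, lgd, y, ly, l1y)
            bn = beta[j] + dz
            lr = ll_new - ll + (beta[j] * beta[j] - bn * bn) / (2.0 * beta_sd * beta_sd)
            alpha = math.exp(min(0.0, lr))
            if np.random.random() < alpha:
                beta[j] = bn
                eta = eta_new
                ll = ll_new
            if adapting:
                lstep[j] += adapt * (alpha - 0.44)
        # --- dispersion coefficients ---
        disp_new = np.zeros(n)
        lgd_new = np.zeros(n)
        for jg in range(2):
            idx = p + jg
            st = math.exp(lstep[idx])
            dz = st * np.random.normal()
            g0n = g0 + dz if jg == 0 else g0
            g1n = g1 + dz if jg == 1 else g1
            if not _set_disp(kind, g0n, g1n, logn, disp_new, lgd_new):
                continue
            ll_new = _loglik_full(kind, eta, disp_new, lgd_new, y, ly, l1y)
            old = g0 if jg == 0 else g1
            new = old + dz
            lr = ll_new - ll + (old * old - new * new) / (2.0 * g_sd * g_sd)
            alpha = math.exp(min(0.0, lr))
            if np.random.random() < alpha:
                g0, g1 = g0n, g1n
                tmp = disp; disp = disp_new; disp_new = tmp
                tmp = lgd; lgd = lgd_new; lgd_new = tmp
                ll = ll_new
            if adapting:
                lstep[idx] += adapt * (alpha - 0.44)
        # --- species effects (MVN prior with precision Pm / sigS^2) ---
        sig2S = math.exp(2.0 * lsigS)
        for js in range(ns):
            idx = p + 2 + js
            st = math.exp(lstep[idx])
            dz = st * np.random.normal()
            lo, hi = sp_ptr[js], sp_ptr[js + 1]
            ll_old_rows = _loglik_rows(kind, eta, disp, lgd, y, ly, l1y, sp_rows, lo, hi)
            for t in range(lo, hi):
                eta[sp_rows[t]] += dz
            ll_new_rows = _loglik_rows(kind, eta, disp, lgd, y, ly, l1y, sp_rows, lo, hi)
            rowdot = 0.0
            for k in range(ns):
                rowdot += Pm[js, k] * S[k]
            dquad = 2.0 * dz * rowdot + dz * dz * Pm[js, js]
            lr = ll_new_rows - ll_old_rows - dquad / (2.0 * sig2S)
            alpha = math.exp(min(0.0, lr))
            if np.random.random() < alpha:
                S[js] += dz
                ll += ll_new_rows - ll_old_rows
                quadS += dquad
            else:
                for t in range(lo, hi):
                    eta[sp_rows[t]] -= dz
            if adapting:
                lstep[idx] += adapt * (alpha - 0.44)
        # --- species scale (half-normal prior on sigma_S) ---
        idx = p + 2 + ns + nr
        st = math.exp(lstep[idx])
        dz = st * np.random.normal()
        lsn = lsigS + dz
        sS_old = math.exp(lsigS)
        sS_new = math.exp(lsn)
        lp_old = -ns * lsigS - quadS / (2.0 * sS_old * sS_old) \
            - sS_old * sS_old / (2.0 * sigs_scale * sigs_scale) + lsigS
        lp_new = -ns * lsn - quadS / (2.0 * sS_new * sS_new) \
            - sS_new * sS_new / (2.0 * sigs_scale * sigs_scale) + lsn
        alpha = math.exp(min(0.0, lp_new - lp_old))
        if np.random.random() < alpha:
            lsigS = lsn
        if adapting:
            lstep[idx] += adapt * (alpha - 0.44)
        # --- region effects (intrinsic CAR prior) ---
        if include_region:
            for jr in range(nr):
                idx = p + 2 + ns + jr
                st = math.exp(lstep[idx])
                dz = st * np.random.normal()
                lo, hi = reg_ptr[jr], reg_ptr[jr + 1]
                ll_old_rows = _loglik_rows(kind, eta, disp, lgd, y, ly, l1y, reg_rows, lo, hi)
                for t in range(lo, hi):
                    eta[reg_rows[t]] += dz
                ll_new_rows = _loglik_rows(kind, eta, disp, lgd, y, ly, l1y, reg_rows, lo, hi)
                rowdot = 0.0
                for k in range(nr):
                    rowdot += Q0[jr, k] * R[k]
                dquad = 2.0 * dz * rowdot + dz * dz * Q0[jr, jr]
                lr = ll_new_rows - ll_old_rows - tauR * dquad / 2.0
                alpha = math.exp(min(0.0, lr))
                if np.random.random() < alpha:
                    R[jr] += dz
                    ll += ll_new_rows - ll_old_rows
                else:
                    for t in range(lo, hi):
                        eta[reg_rows[t]] -= dz
                if adapting:
                    lstep[idx] += adapt * (alpha - 0.44)
            # recentre: shift mean(R) into the intercept (likelihood- and
            # CAR-invariant; Metropolis ratio is the intercept prior only)
            m = R.sum() / nr
            b0n = beta[0] + m
            lr = (beta[0] * beta[0] - b0n * b0n) / (2.0 * beta_sd * beta_sd)
            if np.random.random() < math.exp(min(0.0, lr)):
                beta[0] = b0n
                for k in range(nr):
                    R[k] -= m
            # conjugate Gibbs for the CAR precision
            quadR = 0.0
            for a in range(nr):
                rowdot = 0.0
                for b in range(nr):
                    rowdot += Q0[a, b] * R[b]
                quadR += R[a] * rowdot
            shape = taur_shape + 0.5 * car_rank
            rate = taur_rate + 0.5 * quadR
            tauR = np.random.gamma(shape, 1.0 / rate)
            # ridge moves: trade a latitude-patterned component of R against
            # the latitude coefficients.  The linear predictor changes only
            # through the within-region jitter, so these joint proposals
            # travel the R-vs-latitude posterior ridge that single-site
            # updates cannot.
            for mv in range(2):
                col = lat_col if mv == 0 else lat2_col
                if col < 0:
                    continue
                idx = p + 2 + ns + nr + 1 + 1 + mv
                st = math.exp(lstep[idx])
                dz = st * np.random.normal()
                pat = regc1 if mv == 0 else regc2
                R_new = np.empty(nr)
                for k in range(nr):
                    R_new[k] = R[k] + dz * pat[k]
                bn = beta[col] - dz
                eta_new = eta.copy()
                for k in range(nr):
                    for t in range(reg_ptr[k], reg_ptr[k + 1]):
                        eta_new[reg_rows[t]] += dz * pat[k]
                for i in range(n):
                    eta_new[i] -= dz * X[i, col]
                ll_new = _loglik_full(kind, eta_new, disp, lgd, y, ly, l1y)
                quadR_new = 0.0
                for a in range(nr):
                    rowdot = 0.0
                    for b in range(nr):
                        rowdot += Q0[a, b] * R_new[b]
                    quadR_new += R_new[a] * rowdot
                lr = ll_new - ll \
                    - 0.5 * tauR * (quadR_new - quadR) \
                    + (beta[col] * beta[col] - bn * bn) / (2.0 * beta_sd * beta_sd)
                alpha = math.exp(min(0.0, lr))
                if np.random.random() < alpha:
                    R = R_new
                    beta[col] = bn
                    eta = eta_new
                    ll = ll_new
                    quadR = quadR_new
                if adapting:
                    lstep[idx] += adapt * (alpha - 0.44)
        # shift the species-effect mean into the intercept (likelihood
        # invariant; MVN prior on S and normal prior on the intercept decide)
        idx = p + 2 + ns + nr + 1
        st = math.exp(lstep[idx])
        dz = st * np.random.normal()
        sig2S = math.exp(2.0 * lsigS)
        psum = 0.0
        for b in range(ns):
            psum += Pm_colsum[b] * S[b]
        dquad = 2.0 * dz * psum + dz * dz * Pm_total
        bn = beta[0] - dz
        lr = -dquad / (2.0 * sig2S) \
            + (beta[0] * beta[0] - bn * bn) / (2.0 * beta_sd * beta_sd)
        alpha = math.exp(min(0.0, lr))
        if np.random.random() < alpha:
            for a in range(ns):
                S[a] += dz
            beta[0] = bn
            quadS += dquad
        if adapting:
            lstep[idx] += adapt * (alpha - 0.44)
        # --- store ---
        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            c = 0
            for j in range(p):
                out[kept, c] = beta[j]; c += 1
            for js in range(ns):
                out[kept, c] = S[js]; c += 1
            for jr in range(nr):
                out[kept, c] = R[jr]; c += 1
            out[kept, c] = g0; c += 1
            out[kept, c] = g1; c += 1
            out[kept, c] = math.exp(lsigS); c += 1
            out[kept, c] = tauR if include_region else 0.0
            out_ll[kept] = ll
            kept += 1
    return out, out_ll
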