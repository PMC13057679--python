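"""Single-site Gibbs kernel for the IDL animal model (numba-compiled).

The location vector is ordered [beta | h | r | u | i]:

* beta — fixed effects and covariates (the depression slope c included),
  improper flat priors;
* h, r — i.i.d. permanent-environment and rider effects;
* (u, i) — additive and inbreeding-depression-load effects over *all*
  pedigree animals with joint prior N(0, G kron A), handled through the
  sparse A^-1 (Henderson/Quaas) so a scalar update touches only an animal's
  observations and its A^-1 row.

Scalar variances are drawn from scaled inverse-chi-square full conditionals,
G from a 2x2 inverse Wishart with scale [[u'A^-1 u, u'A^-1 i], [., i'A^-1 i]].
Everything is driven by numpy's legacy RNG seeded once, so a chain is
bitwise-reproducible per seed.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _inv2(a00, a01, a11):
    det = a00 * a11 - a01 * a01
    return a11 / det, -a01 / det, a00 / det


@njit(cache=True)
def _sample_iw2(s00, s01, s11, df):
    """Draw G ~ InvWishart_2(df, S) by Bartlett on W ~ Wishart(df, S^-1)."""
    i00, i01, i11 = _inv2(s00, s01, s11)
    l00 = np.sqrt(i00)
    l10 = i01 / l00
    l11 = np.sqrt(i11 - l10 * l10)
    c00 = np.sqrt(np.random.chisquare(df))
    c10 = np.random.normal()
    c11 = np.sqrt(np.random.chisquare(df - 1.0))
    a00 = l00 * c00
    a10 = l10 * c00 + l11 * c10
    a11 = l11 * c11
    w00 = a00 * a00
    w01 = a00 * a10
    w11 = a10 * a10 + a11 * a11
    return _inv2(w00, w01, w11)


@njit(cache=True, inline="always")
def _update_scalar(j, theta, e, indptr, indices, data, css,
                   inv_se, prior_prec, prior_rhs):
    lo = indptr[j]
    hi = indptr[j + 1]
    old = theta[j]
    dot = 0.0
    for ptr in range(lo, hi):
        dot += data[ptr] * e[indices[ptr]]
    rhs = (dot + css[j] * old) * inv_se + prior_rhs
    prec = css[j] * inv_se + prior_prec
    new = rhs / prec + np.random.normal() / np.sqrt(prec)
    delta = new - old
    theta[j] = new
    for ptr in range(lo, hi):
        e[indices[ptr]] -= data[ptr] * delta


@njit(cache=True)
def run_chain(y, indptr, indices, data, css,
              p_beta, n_h, n_r, n_anim,
              ai_indptr, ai_indices, ai_data,
              n_iter, burn_in, thin, seed,
              nu_e, s2e0, nu_h, s2h0, nu_r, s2r0,
              nu_g, vg00, vg01, vg11,
              g00, g01, g11, sig2_e, sig2_h, sig2_r):
    np.random.seed(seed)
    n = y.shape[0]
    theta = np.zeros(p_beta + n_h + n_r + 2 * n_anim)
    e = y.copy()
    off_h = p_beta
    off_r = p_beta + n_h
    off_u = off_r + n_r
    off_i = off_u + n_anim

    n_keep = 0
    for it in range(n_iter):
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
    draws = np.zeros((n_keep, p_beta + 6))
    u_mean = np.zeros(n_anim)
    i_mean = np.zeros(n_anim)

    gi00, gi01, gi11 = _inv2(g00, g01, g11)
    k = 0
    status = 0
    for it in range(n_iter):
        inv_se = 1.0 / sig2_e
        for j in range(p_beta):
            _update_scalar(j, theta, e, indptr, indices, data, css,
                           inv_se, 0.0, 0.0)
        if n_h > 0:
            lam = 1.0 / sig2_h
            for jj in range(n_h):
                _update_scalar(off_h + jj, theta, e, indptr, indices, data,
                               css, inv_se, lam, 0.0)
        if n_r > 0:
            lam = 1.0 / sig2_r
            for jj in range(n_r):
                _update_scalar(off_r + jj, theta, e, indptr, indices, data,
                               css, inv_se, lam, 0.0)
        for x in range(n_anim):
            # u_x | rest: precision gi00*a_xx, coupling over the A^-1 row
            axx = 0.0
            du = 0.0
            di = 0.0
            for ptr in range(ai_indptr[x], ai_indptr[x + 1]):
                yx = ai_indices[ptr]
                av = ai_data[ptr]
                di += av * theta[off_i + yx]
                if yx == x:
                    axx = av
                else:
                    du += av * theta[off_u + yx]
            _update_scalar(off_u + x, theta, e, indptr, indices, data, css,
                           inv_se, gi00 * axx, -(gi00 * du + gi01 * di))
            axx = 0.0
            du = 0.0
            di = 0.0
            for ptr in range(ai_indptr[x], ai_indptr[x + 1]):
                yx = ai_indices[ptr]
                av = ai_data[ptr]
                du += av * theta[off_u + yx]
                if yx == x:
                    axx = av
                else:
                    di += av * theta[off_i + yx]
            _update_scalar(off_i + x, theta, e, indptr, indices, data, css,
                           inv_se, gi11 * axx, -(gi11 * di + gi01 * du))

        sse = 0.0
        for t in range(n):
            sse += e[t] * e[t]
        sig2_e = (sse + nu_e * s2e0) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sig2_e) or sig2_e <= 1e-300 or sig2_e > 1e300:
            status = -1
            break
        if n_h > 0:
            ss = 0.0
            for jj in range(n_h):
                v = theta[off_h + jj]
                ss += v * v
            sig2_h = (ss + nu_h * s2h0) / np.random.chisquare(n_h + nu_h)
        if n_r > 0:
            ss = 0.0
            for jj in range(n_r):
                v = theta[off_r + jj]
                ss += v * v
            sig2_r = (ss + nu_r * s2r0) / np.random.chisquare(n_r + nu_r)
        if n_anim > 0:
            s00 = vg00
            s01 = vg01
            s11 = vg11
            for x in range(n_anim):
                ux = theta[off_u + x]
                ix = theta[off_i + x]
                for ptr in range(ai_indptr[x], ai_indptr[x + 1]):
                    yx = ai_indices[ptr]
                    av = ai_data[ptr]
                    s00 += ux * av * theta[off_u + yx]
                    s01 += ux * av * theta[off_i + yx]
                    s11 += ix * av * theta[off_i + yx]
            # tiny ridge keeps the scale matrix PD during the first sweeps
            ridge = 1e-10 * (1.0 + s00 + s11)
            s00 += ridge
            s11 += ridge
            df = n_anim + nu_g
            for _attempt in range(25):
                t00, t01, t11 = _sample_iw2(s00, s01, s11, df)
                if t00 > 0.0 and t11 > 0.0 and t00 * t11 - t01 * t01 > 0.0:
                    g00, g01, g11 = t00, t01, t11
                    break
            gi00, gi01, gi11 = _inv2(g00, g01, g11)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p_beta):
                draws[k, j] = theta[j]
            draws[k, p_beta] = g00
            draws[k, p_beta + 1] = g01
            draws[k, p_beta + 2] = g11
            draws[k, p_beta + 3] = sig2_h
            draws[k, p_beta + 4] = sig2_r
            draws[k, p_beta + 5] = sig2_e
            for x in range(n_anim):
                u_mean[x] += theta[off_u + x]
                i_mean[x] += theta[off_i + x]
            k += 1

    if k > 0:
        for x in range(n_anim):
            u_mean[x] /= k
            i_mean[x] /= k
    return draws[:k], u_mean, i_mean, status
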