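"""Compiled parameter-expansion moves for the animal-model sampler.

Numba translation of the per-trait scale moves (slice sampling) and the
shear moves (exact Gaussian draws) applied to one random-effect vector
and its covariance component per sweep.  The randomness is pre-drawn by
the caller so the kernel is deterministic; the mathematical form of the
moves is documented on the pure-Python equivalents in `animal_model`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logf_scale(c, alpha, beta, expo, kappa):
    return -0.5 * (alpha * c * c - 2.0 * beta * c) - expo * np.log(c) - kappa / (
        2.0 * c * c
    )


@njit(cache=True)
def px_component(u, rec_level, d_resid, pat, n_pat, W, comp, s_diag, nu, uniforms, normals):
    """Scale + shear group moves for one component; mutates u and comp."""
    n_rec = rec_level.shape[0]
    n_lev = u.shape[0]
    t = np.empty((n_rec, 4))
    e = np.empty((n_rec, 4))
    for i in range(n_rec):
        lv = rec_level[i]
        for q in range(4):
            t[i, q] = u[lv, q]
            e[i, q] = d_resid[i, q] - t[i, q]
    comp_inv = np.linalg.inv(comp)

    # per-pattern cross-products of mapped effects and residuals
    T = np.zeros((n_pat, 4, 4))
    U = np.zeros((n_pat, 4, 4))
    for i in range(n_rec):
        p = pat[i]
        for q in range(4):
            tq = t[i, q]
            for r in range(4):
                T[p, q, r] += tq * t[i, r]
                U[p, q, r] += tq * d_resid[i, r]

    # per-trait scale moves via slice sampling from the identity
    for k in range(4):
        alpha = 0.0
        beta = 0.0
        for p in range(n_pat):
            alpha += W[p, k, k] * T[p, k, k]
            acc_u = 0.0
            acc_t = 0.0
            for l in range(4):
                acc_u += W[p, k, l] * U[p, k, l]
                acc_t += W[p, k, l] * T[p, k, l]
            beta += acc_u - (acc_t - W[p, k, k] * T[p, k, k])
        if alpha <= 0.0:
            continue
        kappa = s_diag[k] * comp_inv[k, k]
        expo = nu + 1.0
        log_y = _logf_scale(1.0, alpha, beta, expo, kappa) + np.log(uniforms[k, 0])
        width = 2.0 / np.sqrt(alpha)
        lo = 1.0 - width * uniforms[k, 1]
        if lo < 1e-12:
            lo = 1e-12
        hi = lo + width
        for _ in range(20):
            if lo <= 1e-12 or _logf_scale(lo, alpha, beta, expo, kappa) < log_y:
                break
            lo = lo - width
            if lo < 1e-12:
                lo = 1e-12
        for _ in range(20):
            if _logf_scale(hi, alpha, beta, expo, kappa) < log_y:
                break
            hi = hi + width
        c = 1.0
        ui = 2
        for _ in range(50):
            if ui >= uniforms.shape[1]:
                break
            prop = lo + (hi - lo) * uniforms[k, ui]
            ui += 1
            if _logf_scale(prop, alpha, beta, expo, kappa) >= log_y:
                c = prop
                break
            if prop < 1.0:
                lo = prop
            else:
                hi = prop
        if c != 1.0:
            for lv in range(n_lev):
                u[lv, k] *= c
            for q in range(4):
                comp[k, q] *= c
            for q in range(4):
                comp[q, k] *= c
            for q in range(4):
                comp_inv[k, q] /= c
            for q in range(4):
                comp_inv[q, k] /= c
            for i in range(n_rec):
                t[i, k] *= c
                e[i, k] = d_resid[i, k] - t[i, k]
            for p in range(n_pat):
                for q in range(4):
                    T[p, k, q] *= c
                for q in range(4):
                    T[p, q, k] *= c
                for q in range(4):
                    U[p, k, q] *= c

    # shear moves: exact Gaussian draw per ordered trait pair
    z = 0
    for k in range(4):
        for l in range(4):
            if l == k:
                continue
            alpha = 0.0
            beta = 0.0
            for i in range(n_rec):
                p = pat[i]
                tk = t[i, k]
                alpha += W[p, l, l] * tk * tk
                acc = 0.0
                for q in range(4):
                    acc += e[i, q] * W[p, q, l]
                beta += tk * acc
            sk = s_diag[k]
            tau = alpha + sk * comp_inv[l, l]
            if tau <= 0.0:
                z += 1
                continue
            g = (beta + sk * comp_inv[k, l]) / tau + normals[z] / np.sqrt(tau)
            z += 1
            for lv in range(n_lev):
                u[lv, l] += g * u[lv, k]
            for q in range(4):
                comp[l, q] += g * comp[k, q]
            for q in range(4):
                comp[q, l] += g * comp[q, k]
            for q in range(4):
                comp_inv[k, q] -= g * comp_inv[l, q]
            for q in range(4):
                comp_inv[q, k] -= g * comp_inv[q, l]
            for i in range(n_rec):
                e[i, l] -= g * t[i, k]
                t[i, l] += g * t[i, k]


@njit(cache=True)
def sample_batch_nb(gid, pat_counts_u, d_u, rhs, W, comp_inv, z, out):
    """Batched normal full-conditional draws (see _sample_batch)."""
    n_keys = d_u.shape[0]
    n_pat = W.shape[0]
    Pinv = np.empty((n_keys, 4, 4))
    LinvT = np.empty((n_keys, 4, 4))
    for k in range(n_keys):
        P = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                v = d_u[k] * comp_inv[i, j]
                for p in range(n_pat):
                    v += pat_counts_u[k, p] * W[p, i, j]
                P[i, j] = v
        L = np.linalg.cholesky(P)
        Li = np.linalg.inv(L)
        for i in range(4):
            for j in range(4):
                LinvT[k, i, j] = Li[j, i]
        for i in range(4):
            for j in range(4):
                s = 0.0
                for q in range(4):
                    s += Li[q, i] * Li[q, j]
                Pinv[k, i, j] = s
    m = gid.shape[0]
    for i in range(m):
        g = gid[i]
        for r in range(4):
            mean = 0.0
            noise = 0.0
            for c in range(4):
                mean += Pinv[g, r, c] * rhs[i, c]
                noise += LinvT[g, r, c] * z[i, c]
            out[i, r] = mean + noise


@njit(cache=True)
def rinvwishart_nb(scale, chis, norms):
    """Bartlett inverse-Wishart draw from pre-drawn randoms."""
    Ls = np.linalg.cholesky(scale)
    Ls_i = np.linalg.inv(Ls)
    sigma = Ls_i.T @ Ls_i
    C = np.linalg.cholesky(sigma)
    A = np.zeros((4, 4))
    for i in range(4):
        A[i, i] = np.sqrt(chis[i])
    k = 0
    for i in range(1, 4):
        for j in range(i):
            A[i, j] = norms[k]
            k += 1
    T = C @ A
    Ti = np.linalg.inv(T)
    D = Ti.T @ Ti
    return 0.5 * (D + D.T)
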