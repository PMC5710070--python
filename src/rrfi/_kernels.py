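"""Numba kernels for the Gibbs sampler's location-effect sweeps.

All sweeps maintain the running residual vector ``e = y - fitted`` in place:
an effect update removes its old contribution implicitly (the full
conditional is formed from ``e`` plus the effect's own current term) and
subtracts the new one. Standard normal deviates are pre-drawn by the caller
so that all randomness flows through one seeded generator.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_scalar(e, theta, rptr, ridx, w, inv_prior, inv_ve, zs):
    """Single-site updates of one scalar effect family.

    Levels are laid out CSR-style: level l owns records ridx[rptr[l]:rptr[l+1]]
    with covariate values w aligned to ridx. ``inv_prior`` is 1/prior-variance
    (0 for an effect with a flat prior).
    """
    for l in range(theta.size):
        sw2 = 0.0
        swr = 0.0
        for t in range(rptr[l], rptr[l + 1]):
            r = ridx[t]
            wr = w[t]
            sw2 += wr * wr
            swr += wr * (e[r] + wr * theta[l])
        prec = sw2 * inv_ve + inv_prior
        if prec <= 0.0:
            continue
        new = swr * inv_ve / prec + zs[l] / np.sqrt(prec)
        diff = new - theta[l]
        theta[l] = new
        for t in range(rptr[l], rptr[l + 1]):
            e[ridx[t]] -= w[t] * diff


@njit(cache=True)
def _chol_sample(P, rhs, zs, out):
    """out = P^{-1} rhs + L^{-T} zs with P = L L' (small k, in-place)."""
    k = P.shape[0]
    L = np.zeros((k, k))
    for c in range(k):
        s = P[c, c]
        for d in range(c):
            s -= L[c, d] * L[c, d]
        L[c, c] = np.sqrt(s)
        for r in range(c + 1, k):
            s = P[r, c]
            for d in range(c):
                s -= L[r, d] * L[c, d]
            L[r, c] = s / L[c, c]
    # forward solve L u = rhs
    u = np.empty(k)
    for c in range(k):
        s = rhs[c]
        for d in range(c):
            s -= L[c, d] * u[d]
        u[c] = s / L[c, c]
    # back solve L' m = u, and L' t = zs for the stochastic part
    for c in range(k - 1, -1, -1):
        s = u[c] + zs[c]
        for d in range(c + 1, k):
            s -= L[d, c] * out[d]
        out[c] = s / L[c, c]


@njit(cache=True)
def sweep_genetic(
    e, a, z, arptr, aridx, M, Ginv, inv_ve, indptr, indices, data, zs
):
    """Blocked update of every animal's k-vector of genetic effects.

    Full conditional of animal i: precision M_i/ve + A^{-1}_{ii} Ginv, with
    the usual pedigree neighbour term -Ginv sum_{j!=i} A^{-1}_{ij} a_j on the
    right-hand side. M_i = sum_r z_r z_r' over the animal's records is
    precomputed; ancestors have empty record ranges.
    """
    n_ped, k = a.shape
    nb = np.empty(k)
    rhs = np.empty(k)
    P = np.empty((k, k))
    new = np.empty(k)
    for i in range(n_ped):
        dii = 0.0
        for c in range(k):
            nb[c] = 0.0
        for t in range(indptr[i], indptr[i + 1]):
            j = indices[t]
            v = data[t]
            if j == i:
                dii = v
            else:
                for c in range(k):
                    nb[c] += v * a[j, c]
        for c in range(k):
            rhs[c] = 0.0
        for t in range(arptr[i], arptr[i + 1]):
            r = aridx[t]
            resid = e[r]
            for c in range(k):
                resid += z[r, c] * a[i, c]
            for c in range(k):
                rhs[c] += z[r, c] * resid
        for c in range(k):
            s = 0.0
            for d in range(k):
                s += Ginv[c, d] * nb[d]
                P[c, d] = M[i, c, d] * inv_ve + dii * Ginv[c, d]
            rhs[c] = rhs[c] * inv_ve - s
        _chol_sample(P, rhs, zs[i], new)
        for t in range(arptr[i], arptr[i + 1]):
            r = aridx[t]
            dres = 0.0
            for c in range(k):
                dres += z[r, c] * (new[c] - a[i, c])
            e[r] -= dres
        for c in range(k):
            a[i, c] = new[c]


@njit(cache=True)
def sweep_permanent(e, p, z, prptr, pridx, M, Pinv, inv_ve, zs):
    """Blocked update of permanent-environmental k-vectors (identity prior)."""
    n_rec, k = p.shape
    rhs = np.empty(k)
    P = np.empty((k, k))
    new = np.empty(k)
    for i in range(n_rec):
        for c in range(k):
            rhs[c] = 0.0
        for t in range(prptr[i], prptr[i + 1]):
            r = pridx[t]
            resid = e[r]
            for c in range(k):
                resid += z[r, c] * p[i, c]
            for c in range(k):
                rhs[c] += z[r, c] * resid
        for c in range(k):
            for d in range(k):
                P[c, d] = M[i, c, d] * inv_ve + Pinv[c, d]
            rhs[c] = rhs[c] * inv_ve
        _chol_sample(P, rhs, zs[i], new)
        for t in range(prptr[i], prptr[i + 1]):
            r = pridx[t]
            dres = 0.0
            for c in range(k):
                dres += z[r, c] * (new[c] - p[i, c])
            e[r] -= dres
        for c in range(k):
            p[i, c] = new[c]
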