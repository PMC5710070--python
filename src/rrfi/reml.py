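"""EM-REML variance estimation and BLUP of breeding values.

The mixed-model equations (MME) are assembled sparse:

    [W'W + var_e * Q] theta = W'y

where W stacks all design columns (batch-week classes, fixed regressions,
pen, batch-week random regressions, genetic and permanent animal blocks)
and Q holds the prior precisions: 0 for fixed columns, I/v for scalar
families, Ainv (x) G0^{-1} for the genetic block (animal-major ordering) and
I (x) P0^{-1} for the permanent block.

EM-REML alternates MME solutions with the classical expectation updates
built from prediction-error (co)variances, which requires the inverse of
the coefficient matrix and is therefore restricted to desk-scale systems;
BLUP solving alone is sparse and scales much further.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .model import DesignSystem, EffectSet, VarianceComponents

__all__ = [
    "build_w", "build_prior_precision", "solve_mme",
    "predict_breeding_values", "em_reml", "reml_loglik", "RemlResult",
]

_GAMMA_TERMS = ("mw", "wg", "fg")


def _offsets(system: DesignSystem) -> dict:
    """Column offsets of each effect block in W."""
    k = system.spec.k
    off = {}
    pos = 0
    off["ba"] = (pos, system.n_ba)
    pos += system.n_ba
    nb = 3 * system.n_week if system.with_fixed_reg else 0
    off["beta"] = (pos, nb)
    pos += nb
    off["pen"] = (pos, system.n_pen)
    pos += system.n_pen
    ng = 3 * system.n_ba if system.with_gamma else 0
    off["gamma"] = (pos, ng)
    pos += ng
    off["a"] = (pos, system.n_ped * k)
    pos += system.n_ped * k
    off["p"] = (pos, system.n_rec_animals * k)
    pos += system.n_rec_animals * k
    off["total"] = (0, pos)
    return off


def build_w(system: DesignSystem) -> tuple:
    """Sparse design matrix W (n x p) and its column offsets."""
    off = _offsets(system)
    n = system.n
    k = system.spec.k
    rows, cols, vals = [], [], []
    rr = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(rr, off["ba"][0] + system.ba_idx, np.ones(n))
    if system.with_fixed_reg:
        for c in range(3):
            add(rr, off["beta"][0] + 3 * system.week_idx + c, system.x[:, c])
    add(rr, off["pen"][0] + system.pen_idx, np.ones(n))
    if system.with_gamma:
        for c in range(3):
            add(rr, off["gamma"][0] + 3 * system.ba_idx + c, system.x[:, c])
    for j in range(k):
        add(rr, off["a"][0] + k * system.anim_idx + j, system.z[:, j])
        add(rr, off["p"][0] + k * system.rec_idx + j, system.z[:, j])

    w = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, off["total"][1]),
    )
    return w, off


def build_prior_precision(system: DesignSystem, vc: VarianceComponents) -> sparse.csr_matrix:
    """Block prior precision Q (fixed blocks contribute zero)."""
    off = _offsets(system)
    p = off["total"][1]
    blocks = []
    blocks.append(sparse.csr_matrix((off["ba"][1] + off["beta"][1],
                                     off["ba"][1] + off["beta"][1])))
    blocks.append(sparse.identity(system.n_pen, format="csr") / vc.var_pen)
    if system.with_gamma:
        d = np.empty(3 * system.n_ba)
        for c, t in enumerate(_GAMMA_TERMS):
            d[c::3] = 1.0 / vc.var_gamma[t]
        blocks.append(sparse.diags(d, format="csr"))
    G0inv = np.linalg.inv(vc.G0)
    P0inv = np.linalg.inv(vc.P0)
    blocks.append(sparse.kron(system.ainv, G0inv, format="csr"))
    blocks.append(sparse.kron(
        sparse.identity(system.n_rec_animals), P0inv, format="csr"))
    q = sparse.block_diag(blocks, format="csr")
    assert q.shape == (p, p)
    return q


def _unpack(system: DesignSystem, theta: np.ndarray, off: dict) -> EffectSet:
    k = system.spec.k
    eff = EffectSet.zeros(system)
    s, n = off["ba"]
    eff.ba = theta[s: s + n]
    if system.with_fixed_reg:
        s, n = off["beta"]
        eff.beta = theta[s: s + n].reshape(system.n_week, 3)
    s, n = off["pen"]
    eff.pen = theta[s: s + n]
    if system.with_gamma:
        s, n = off["gamma"]
        eff.gamma = theta[s: s + n].reshape(system.n_ba, 3)
    s, n = off["a"]
    eff.a = theta[s: s + n].reshape(system.n_ped, k)
    s, n = off["p"]
    eff.p = theta[s: s + n].reshape(system.n_rec_animals, k)
    return eff


def solve_mme(system: DesignSystem, vc: VarianceComponents) -> tuple:
    """Solve the MME at fixed components; returns (EffectSet, theta, W, offsets).

    Small systems go through a direct sparse factorization; large ones use
    Jacobi-preconditioned conjugate gradients (the MME matrix is SPD), which
    avoids the factorization fill-in of pedigree-structured systems.
    """
    w, off = build_w(system)
    q = build_prior_precision(system, vc)
    m = (w.T @ w) + vc.var_e * q
    rhs = w.T @ system.y
    # tiny ridge on the fixed block guards rank-deficient class layouts
    nf = off["ba"][1] + off["beta"][1]
    ridge = sparse.diags(
        np.concatenate([np.full(nf, 1e-8), np.zeros(m.shape[0] - nf)])
    )
    m = (m + ridge).tocsr()
    if m.shape[0] <= 2000:
        try:
            lu = splu(m.tocsc())
        except RuntimeError as exc:  # singular factorization
            raise np.linalg.LinAlgError(f"MME coefficient matrix singular: {exc}")
        theta = lu.solve(rhs)
    else:
        d = m.diagonal()
        d[d <= 0] = 1.0
        theta, info = cg(
            m, rhs, rtol=1e-10, atol=0.0, maxiter=20_000,
            M=sparse.diags(1.0 / d),
        )
        if info != 0:
            raise np.linalg.LinAlgError(f"PCG failed to converge (info={info})")
    return _unpack(system, theta, off), theta, w, off


def predict_breeding_values(
    system: DesignSystem, vc: VarianceComponents
) -> EffectSet:
    """BLUP of all effects at the given variance components.

    Genetic solutions cover every pedigree animal (ancestors and animals
    without records included, through the relationship structure).
    """
    eff, _, _, _ = solve_mme(system, vc)
    return eff


@dataclass
class RemlResult:
    components: VarianceComponents
    effects: EffectSet
    converged: bool
    n_iter: int
    history: list  # per-iteration dict of component summaries


def em_reml(
    system: DesignSystem,
    start: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    dense_limit: int = 2500,
    track_loglik: bool = False,
) -> RemlResult:
    """EM-REML for all variance components of a design system.

    Expectation steps use prediction-error (co)variances from the dense
    inverse of the MME coefficient matrix, so the total number of unknowns
    must stay below ``dense_limit``. Convergence: maximum relative change
    of any component below ``tol``. A non-convergent run returns the last
    iterate with ``converged=False``.
    """
    from .inference import default_start

    vc = (start or default_start(system)).copy()
    w, off = build_w(system)
    p = off["total"][1]
    if p > dense_limit:
        raise ValueError(
            f"{p} unknowns exceed dense_limit={dense_limit}; EM-REML needs "
            "the inverse coefficient matrix"
        )
    wtw = (w.T @ w).toarray()
    wty = w.T @ system.y
    yty = float(system.y @ system.y)
    n = system.n
    k = system.spec.k
    nf = off["ba"][1] + off["beta"][1]
    rank_f = int(np.linalg.matrix_rank(wtw[:nf, :nf]))
    ainv_coo = system.ainv.tocoo()

    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = build_prior_precision(system, vc).toarray()
        m = wtw + vc.var_e * q
        m[:nf, :nf] += 1e-8 * np.eye(nf)
        minv = np.linalg.inv(m)
        theta = minv @ wty
        c = vc.var_e * minv  # prediction-error (co)variance matrix
        eff = _unpack(system, theta, off)

        new = vc.copy()
        # residual
        new.var_e = (yty - float(theta @ wty)) / (n - rank_f)
        # pen
        s0, np_pen = off["pen"]
        cp = c[s0: s0 + np_pen, s0: s0 + np_pen]
        new.var_pen = (float(eff.pen @ eff.pen) + float(np.trace(cp))) / np_pen
        # gamma
        if system.with_gamma:
            s0, ng = off["gamma"]
            for ci, t in enumerate(_GAMMA_TERMS):
                idx = np.arange(s0 + ci, s0 + ng, 3)
                u = theta[idx]
                new.var_gamma[t] = (
                    float(u @ u) + float(np.trace(c[np.ix_(idx, idx)]))
                ) / system.n_ba
        # G0: (a' Ainv a + trace terms) / n_ped
        s0, _ = off["a"]
        G0n = np.empty((k, k))
        for si in range(k):
            for ti in range(si, k):
                rowsi = s0 + k * ainv_coo.row + si
                colst = s0 + k * ainv_coo.col + ti
                tr = float(np.sum(ainv_coo.data * c[colst, rowsi]))
                quad = float(eff.a[:, si] @ (system.ainv @ eff.a[:, ti]))
                G0n[si, ti] = G0n[ti, si] = (quad + tr) / system.n_ped
        new.G0 = G0n
        # P0
        s0, _ = off["p"]
        P0n = np.empty((k, k))
        nrec = system.n_rec_animals
        for si in range(k):
            for ti in range(si, k):
                idx_s = s0 + k * np.arange(nrec) + si
                idx_t = s0 + k * np.arange(nrec) + ti
                tr = float(np.sum(c[idx_s, idx_t]))
                quad = float(eff.p[:, si] @ eff.p[:, ti])
                P0n[si, ti] = P0n[ti, si] = (quad + tr) / nrec
        new.P0 = P0n

        def relchange(a, b):
            denom = max(abs(a), abs(b), 1e-12)
            return abs(a - b) / denom

        deltas = [relchange(new.var_e, vc.var_e), relchange(new.var_pen, vc.var_pen)]
        deltas += [relchange(new.G0[i, i], vc.G0[i, i]) for i in range(k)]
        deltas += [relchange(new.P0[i, i], vc.P0[i, i]) for i in range(k)]
        if system.with_gamma:
            deltas += [relchange(new.var_gamma[t], vc.var_gamma[t])
                       for t in _GAMMA_TERMS]
        rec = {"iter": it, "var_e": new.var_e, "max_rel_change": max(deltas)}
        if track_loglik:
            rec["loglik"] = reml_loglik(system, new)
        history.append(rec)
        vc = new
        if max(deltas) < tol:
            converged = True
            break

    eff, _, _, _ = solve_mme(system, vc)
    return RemlResult(components=vc, effects=eff, converged=converged,
                      n_iter=it, history=history)


def reml_loglik(system: DesignSystem, vc: VarianceComponents) -> float:
    """Restricted log-likelihood by direct dense evaluation (small n only).

    ln L_R = -1/2 [ log|V| + log|X'V^{-1}X| + y'Py ] up to a constant, with
    V the marginal record covariance and X the fixed-effect columns.
    """
    n = system.n
    if n > 4000:
        raise ValueError("dense REML log-likelihood limited to small systems")
    w, off = build_w(system)
    nf = off["ba"][1] + off["beta"][1]
    wd = w.toarray()
    xf = wd[:, :nf]
    zr = wd[:, nf:]
    q = build_prior_precision(system, vc).toarray()[nf:, nf:]
    gmat = np.linalg.inv(q + 1e-12 * np.eye(q.shape[0]))
    v = zr @ gmat @ zr.T + vc.var_e * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(v)
    vinv = np.linalg.inv(v)
    xtvx = xf.T @ vinv @ xf
    # use pseudo-determinant on the fixed block (rank-deficient layouts)
    ev = np.linalg.eigvalsh(xtvx)
    ev = ev[ev > 1e-8 * ev.max()]
    logdet_x = float(np.sum(np.log(ev)))
    beta = np.linalg.lstsq(xtvx, xf.T @ vinv @ system.y, rcond=None)[0]
    r = system.y - xf @ beta
    quad = float(r @ vinv @ system.y)
    return -0.5 * (logdet_v + logdet_x + quad)
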