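"""Bayesian estimation of the random-regression models by Gibbs sampling.

Location effects have multivariate-normal full conditionals and are updated
in single-site (scalar families) or per-animal blocked (genetic, permanent)
sweeps. Variance components carry bounded-uniform (flat) priors over the
valid parameter space, so their full conditionals are scaled inverse
chi-square (scalars) and inverse-Wishart-form (G0, P0); draws outside the
configured bounds are rejected and redrawn. The conditional deviance is
tracked for DIC model comparison, and marginal posteriors are summarized by
mean / median / sd / 95% HPD interval / Pr(>0) / effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .model import DesignSystem, EffectSet, VarianceComponents

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "ModelFitSummary",
    "gibbs_sample",
    "dic",
    "summarize_posterior",
    "hpd_interval",
    "effective_sample_size",
    "default_start",
    "vc_param_names",
    "vc_from_draw",
]


@dataclass
class ChainConfig:
    """MCMC protocol. The desk-scale default (50k iterations, 10k burn-in,
    thin 10, 2 chains) keeps full analyses in minutes; the long protocol
    (1e6 iterations, 1e5 burn-in, thin 100, 5 chains) is available through
    the same fields."""

    n_iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    n_chains: int = 2
    seed: int = 0
    start: VarianceComponents | None = None
    bounds: dict | None = None  # name -> (low, high) for scalar variances
    max_reject: int = 1000

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class ModelFitSummary:
    """DIC decomposition: dic = mean_deviance + p_d,
    p_d = mean_deviance - deviance_at_mean."""

    dic: float
    mean_deviance: float
    deviance_at_mean: float
    p_d: float


@dataclass
class PosteriorSamples:
    """Thinned draws of all variance components (plus deviance) per chain,
    and the running posterior mean of every location effect."""

    names: list
    chains: list                       # list of (n_draws, n_params) arrays
    effect_mean: EffectSet
    spec_code: int
    n_records: int
    config: ChainConfig

    def merged(self) -> np.ndarray:
        return np.vstack(self.chains)

    def get(self, name: str, chain: int | None = None) -> np.ndarray:
        j = self.names.index(name)
        if chain is None:
            return self.merged()[:, j]
        return self.chains[chain][:, j]

    @property
    def n_draws_total(self) -> int:
        return sum(c.shape[0] for c in self.chains)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, draw, parameter, value."""
        rows = []
        for c, arr in enumerate(self.chains):
            df = pd.DataFrame(arr, columns=self.names)
            df.insert(0, "draw", np.arange(arr.shape[0]))
            df.insert(0, "chain", c)
            rows.append(df.melt(id_vars=["chain", "draw"], var_name="parameter"))
        return pd.concat(rows, ignore_index=True)


def vc_param_names(system: DesignSystem) -> list:
    names = []
    eff = system.spec.effect_names
    k = system.spec.k
    for i in range(k):
        for j in range(i, k):
            names.append(f"G0[{eff[i]},{eff[j]}]")
    for i in range(k):
        for j in range(i, k):
            names.append(f"P0[{eff[i]},{eff[j]}]")
    if system.with_gamma:
        for t in ("mw", "wg", "fg"):
            names.append(f"var_gamma_{t}")
    names.append("var_pen")
    names.append("var_e")
    names.append("deviance")
    return names


def _pack_draw(system, G0, P0, var_gamma, var_pen, var_e, deviance):
    k = G0.shape[0]
    vals = [G0[i, j] for i in range(k) for j in range(i, k)]
    vals += [P0[i, j] for i in range(k) for j in range(i, k)]
    if system.with_gamma:
        vals += list(var_gamma)
    vals += [var_pen, var_e, deviance]
    return vals


def vc_from_draw(samples: PosteriorSamples, draws: np.ndarray, spec) -> VarianceComponents:
    """Rebuild a VarianceComponents object from one packed draw row."""
    k = spec.k
    names = samples.names
    row = dict(zip(names, draws))
    eff = spec.effect_names
    G0 = np.empty((k, k))
    P0 = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            G0[i, j] = G0[j, i] = row[f"G0[{eff[i]},{eff[j]}]"]
            P0[i, j] = P0[j, i] = row[f"P0[{eff[i]},{eff[j]}]"]
    var_gamma = {
        t: row[f"var_gamma_{t}"] for t in ("mw", "wg", "fg") if f"var_gamma_{t}" in row
    }
    return VarianceComponents(
        spec=spec, G0=G0, P0=P0, var_pen=row["var_pen"], var_e=row["var_e"],
        var_gamma=var_gamma,
    )


def default_start(system: DesignSystem) -> VarianceComponents:
    """Heuristic starting components from the phenotypic variance."""
    vy = float(np.var(system.y))
    k = system.spec.k
    G0 = np.diag([0.10 * vy] + [0.02 * vy] * (k - 1))
    P0 = np.diag([0.15 * vy] + [0.02 * vy] * (k - 1))
    return VarianceComponents(
        spec=system.spec,
        G0=G0,
        P0=P0,
        var_pen=0.05 * vy,
        var_e=0.5 * vy,
        var_gamma={t: 0.02 * vy for t in ("mw", "wg", "fg")},
    )


def _by_level(level_idx: np.ndarray, n_levels: int, w: np.ndarray):
    order = np.argsort(level_idx, kind="stable").astype(np.int64)
    counts = np.bincount(level_idx, minlength=n_levels)
    rptr = np.zeros(n_levels + 1, dtype=np.int64)
    np.cumsum(counts, out=rptr[1:])
    return rptr, order, np.ascontiguousarray(w[order])


def _block_crossprods(z, rptr, ridx, n_units, k):
    M = np.zeros((n_units, k, k))
    for i in range(n_units):
        rows = ridx[rptr[i]: rptr[i + 1]]
        if rows.size:
            zi = z[rows]
            M[i] = zi.T @ zi
    return M


def _bounded_scalar(rng, ssq, df, bounds, max_reject, label):
    """Draw ssq / chi2(df), rejecting outside the prior bounds."""
    lo, hi = bounds if bounds is not None else (0.0, np.inf)
    for _ in range(max_reject):
        v = ssq / rng.chisquare(df)
        if lo <= v <= hi:
            return v
    raise RuntimeError(f"variance draw for {label} rejected {max_reject} times")


def _run_chain(system: DesignSystem, config: ChainConfig, seed_seq) -> tuple:
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    spec = system.spec
    k = spec.k
    n = system.n
    y = system.y
    x = system.x
    z = np.ascontiguousarray(system.z)

    vc = (config.start or default_start(system)).copy()
    vc.validate_pd()
    bounds = config.bounds or {}

    # CSR layouts per effect family
    ba_rptr, ba_ridx, ba_w = _by_level(system.ba_idx, system.n_ba, np.ones(n))
    beta_lay = [
        _by_level(system.week_idx, system.n_week, x[:, c]) for c in range(3)
    ]
    pen_rptr, pen_ridx, pen_w = _by_level(system.pen_idx, system.n_pen, np.ones(n))
    gamma_lay = [
        _by_level(system.ba_idx, system.n_ba, x[:, c]) for c in range(3)
    ]
    a_rptr_rec, a_ridx, _ = _by_level(system.anim_idx, system.n_ped, np.ones(n))
    p_rptr, p_ridx, _ = _by_level(system.rec_idx, system.n_rec_animals, np.ones(n))
    Ma = _block_crossprods(z, a_rptr_rec, a_ridx, system.n_ped, k)
    Mp = _block_crossprods(z, p_rptr, p_ridx, system.n_rec_animals, k)
    ainv = system.ainv.tocsr()
    indptr = ainv.indptr.astype(np.int64)
    indices = ainv.indices.astype(np.int64)
    data = ainv.data.astype(np.float64)

    eff = EffectSet.zeros(system)
    # start BA at cell means so the residual starts centred
    sums = np.bincount(system.ba_idx, weights=y, minlength=system.n_ba)
    cnts = np.bincount(system.ba_idx, minlength=system.n_ba)
    eff.ba = sums / np.maximum(cnts, 1)
    e = y - eff.ba[system.ba_idx]

    names = vc_param_names(system)
    draws = np.empty((config.n_draws, len(names)))
    eff_sum = EffectSet.zeros(system)
    n_kept = 0

    n_ped = system.n_ped
    n_rec = system.n_rec_animals
    if n_ped <= 2 * k or n_rec <= 2 * k:
        raise ValueError("too few animals for flat-prior covariance sampling")

    for it in range(1, config.n_iterations + 1):
        inv_ve = 1.0 / vc.var_e
        Ginv = np.linalg.inv(vc.G0)
        Pinv = np.linalg.inv(vc.P0)

        _kernels.sweep_scalar(
            e, eff.ba, ba_rptr, ba_ridx, ba_w, 0.0, inv_ve,
            rng.standard_normal(system.n_ba),
        )
        if system.with_fixed_reg:
            for c in range(3):
                rptr, ridx, w = beta_lay[c]
                theta = np.ascontiguousarray(eff.beta[:, c])
                _kernels.sweep_scalar(
                    e, theta, rptr, ridx, w, 0.0, inv_ve,
                    rng.standard_normal(system.n_week),
                )
                eff.beta[:, c] = theta
        _kernels.sweep_scalar(
            e, eff.pen, pen_rptr, pen_ridx, pen_w, 1.0 / vc.var_pen, inv_ve,
            rng.standard_normal(system.n_pen),
        )
        if system.with_gamma:
            for c, t in enumerate(("mw", "wg", "fg")):
                rptr, ridx, w = gamma_lay[c]
                theta = np.ascontiguousarray(eff.gamma[:, c])
                _kernels.sweep_scalar(
                    e, theta, rptr, ridx, w, 1.0 / vc.var_gamma[t], inv_ve,
                    rng.standard_normal(system.n_ba),
                )
                eff.gamma[:, c] = theta
        _kernels.sweep_genetic(
            e, eff.a, z, a_rptr_rec, a_ridx, Ma, Ginv, inv_ve,
            indptr, indices, data, rng.standard_normal((n_ped, k)),
        )
        _kernels.sweep_permanent(
            e, eff.p, z, p_rptr, p_ridx, Mp, Pinv, inv_ve,
            rng.standard_normal((n_rec, k)),
        )

        # --- variance components (flat priors) ---
        Sg = eff.a.T @ (ainv @ eff.a)
        Sg = 0.5 * (Sg + Sg.T) + 1e-10 * np.trace(Sg) / k * np.eye(k)
        vc.G0 = stats.invwishart.rvs(df=n_ped - k - 1, scale=Sg, random_state=rng)
        vc.G0 = np.atleast_2d(vc.G0)
        Sp = eff.p.T @ eff.p
        Sp = 0.5 * (Sp + Sp.T) + 1e-10 * np.trace(Sp) / k * np.eye(k)
        vc.P0 = np.atleast_2d(
            stats.invwishart.rvs(df=n_rec - k - 1, scale=Sp, random_state=rng)
        )
        vc.var_pen = _bounded_scalar(
            rng, float(eff.pen @ eff.pen), system.n_pen - 2,
            bounds.get("var_pen"), config.max_reject, "var_pen",
        )
        if system.with_gamma:
            for c, t in enumerate(("mw", "wg", "fg")):
                vc.var_gamma[t] = _bounded_scalar(
                    rng, float(eff.gamma[:, c] @ eff.gamma[:, c]), system.n_ba - 2,
                    bounds.get(f"var_gamma_{t}"), config.max_reject, f"var_gamma_{t}",
                )
        sse = float(e @ e)
        vc.var_e = _bounded_scalar(
            rng, sse, n - 2, bounds.get("var_e"), config.max_reject, "var_e",
        )

        kept = it > config.burn_in and (it - config.burn_in) % config.thinning == 0
        if kept and n_kept < draws.shape[0]:
            deviance = n * np.log(2 * np.pi * vc.var_e) + sse / vc.var_e
            draws[n_kept] = _pack_draw(
                system, vc.G0, vc.P0,
                [vc.var_gamma[t] for t in ("mw", "wg", "fg")],
                vc.var_pen, vc.var_e, deviance,
            )
            n_kept += 1
            eff_sum.ba += eff.ba
            eff_sum.beta += eff.beta
            eff_sum.pen += eff.pen
            eff_sum.gamma += eff.gamma
            eff_sum.a += eff.a
            eff_sum.p += eff.p

    for arr in (eff_sum.ba, eff_sum.beta, eff_sum.pen, eff_sum.gamma,
                eff_sum.a, eff_sum.p):
        arr /= max(n_kept, 1)
    return draws[:n_kept], eff_sum


def gibbs_sample(system: DesignSystem, config: ChainConfig) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains and collect thinned draws."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    eff_means = []
    for c in range(config.n_chains):
        draws, eff_mean = _run_chain(system, config, seeds[c])
        chains.append(draws)
        eff_means.append(eff_mean)
    # average location-effect means over chains
    merged_eff = EffectSet.zeros(system)
    for em in eff_means:
        merged_eff.ba += em.ba / len(eff_means)
        merged_eff.beta += em.beta / len(eff_means)
        merged_eff.pen += em.pen / len(eff_means)
        merged_eff.gamma += em.gamma / len(eff_means)
        merged_eff.a += em.a / len(eff_means)
        merged_eff.p += em.p / len(eff_means)
    return PosteriorSamples(
        names=vc_param_names(system),
        chains=chains,
        effect_mean=merged_eff,
        spec_code=system.spec.code,
        n_records=system.n,
        config=config,
    )


def dic(system: DesignSystem, samples: PosteriorSamples) -> ModelFitSummary:
    """Deviance information criterion from the conditional normal deviance.

    D(theta) = -2 log p(y | effects, var_e); DIC = mean(D) + p_d with
    p_d = mean(D) - D(posterior means).
    """
    if samples.n_draws_total < 50:
        raise ValueError("need at least 50 retained draws for DIC")
    from .model import predicted_mean

    dbar = float(np.mean(samples.get("deviance")))
    ve_bar = float(np.mean(samples.get("var_e")))
    resid = system.y - predicted_mean(system, samples.effect_mean)
    d_at_mean = system.n * np.log(2 * np.pi * ve_bar) + float(resid @ resid) / ve_bar
    p_d = dbar - d_at_mean
    return ModelFitSummary(
        dic=dbar + p_d, mean_deviance=dbar, deviance_at_mean=d_at_mean, p_d=p_d
    )


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple:
    """Shortest interval containing ``prob`` of the draws."""
    s = np.sort(np.asarray(draws))
    n = s.size
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m:] - s[: n - m]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m])


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    if np.allclose(x, 0):
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive (Geyer's initial positive sequence)
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))


def summarize_posterior(
    samples_or_draws, names=None, prob: float = 0.95
) -> pd.DataFrame:
    """Posterior summary table (chains merged before summarizing).

    Accepts a PosteriorSamples (optionally restricted to ``names``) or a
    mapping / DataFrame of named draw arrays. ESS is computed per chain and
    summed when chain structure is available.
    """
    if isinstance(samples_or_draws, PosteriorSamples):
        samples = samples_or_draws
        use = names if names is not None else samples.names
        per_chain = {nm: [c[:, samples.names.index(nm)] for c in samples.chains]
                     for nm in use}
    else:
        items = dict(samples_or_draws)
        per_chain = {nm: [np.asarray(v)] for nm, v in items.items()}
        use = list(per_chain)
    rows = []
    for nm in use:
        chains = per_chain[nm]
        merged = np.concatenate(chains)
        if merged.size == 0:
            raise ValueError(f"no draws for parameter {nm}")
        lo, hi = hpd_interval(merged, prob)
        rows.append({
            "parameter": nm,
            "mean": float(np.mean(merged)),
            "median": float(np.median(merged)),
            "sd": float(np.std(merged, ddof=1)) if merged.size > 1 else 0.0,
            "hpd_low": lo,
            "hpd_high": hi,
            "prob_gt_zero": float(np.mean(merged > 0)),
            "ess": float(sum(effective_sample_size(c) for c in chains)),
        })
    return pd.DataFrame(rows).set_index("parameter")
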