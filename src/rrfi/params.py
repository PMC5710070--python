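"""Genetic-parameter summaries for the feed-efficiency components.

Heritability of the intercept (residual feed intake, evaluated at the
covariate means, which are zero after standardization):

    h2_RFI = G0[int,int] / (G0[int,int] + P0[int,int] + var_pen + var_e)

Slope "heritabilities" are the additive share of the individual variation
of each component, G0[j,j] / (G0[j,j] + P0[j,j]). Conditional parameters
along a covariate x (sd units, other covariates at 0) follow from the
quadratic forms

    sigma2_a(x) = G0[1,1] + 2 x G0[1,j] + x^2 G0[j,j]

and the permanent analogue; the phenotypic denominator adds pen and
residual variances (batch-week regression variances are treated as
environmental context and excluded throughout, matching the intercept
definition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import PosteriorSamples, summarize_posterior
from .model import ModelSpec, VarianceComponents

__all__ = [
    "heritability_intercept",
    "slope_variance_ratio",
    "genetic_correlations",
    "h2_at_covariate",
    "variance_partition_percent",
    "derived_draws",
    "posterior_genetic_summary",
]


def heritability_intercept(vc: VarianceComponents) -> float:
    denom = vc.G0[0, 0] + vc.P0[0, 0] + vc.var_pen + vc.var_e
    if denom <= 0:
        raise ValueError("nonpositive phenotypic variance")
    return float(vc.G0[0, 0] / denom)


def _slope_index(spec: ModelSpec, term: str) -> int:
    if term not in spec.animal_terms:
        raise ValueError(f"covariate {term!r} has no animal slope in model {spec.code}")
    return 1 + spec.animal_terms.index(term)


def slope_variance_ratio(vc: VarianceComponents, term: str) -> float:
    j = _slope_index(vc.spec, term)
    denom = vc.G0[j, j] + vc.P0[j, j]
    if denom <= 0:
        raise ValueError("nonpositive slope variance")
    return float(vc.G0[j, j] / denom)


def genetic_correlations(vc: VarianceComponents) -> np.ndarray:
    np.linalg.cholesky(vc.G0)  # PD check
    sd = np.sqrt(np.diag(vc.G0))
    return vc.G0 / np.outer(sd, sd)


def h2_at_covariate(vc: VarianceComponents, term: str, x: float) -> tuple:
    """(h2, genetic variance, phenotypic variance) at covariate value x."""
    if not np.isfinite(x):
        raise ValueError("x must be finite")
    j = _slope_index(vc.spec, term)
    va = vc.G0[0, 0] + 2 * x * vc.G0[0, j] + x * x * vc.G0[j, j]
    vp_perm = vc.P0[0, 0] + 2 * x * vc.P0[0, j] + x * x * vc.P0[j, j]
    vp = va + vp_perm + vc.var_pen + vc.var_e
    return float(va / vp), float(va), float(vp)


def variance_partition_percent(sum_model_a: float, sum_model_b: float) -> float:
    """Share (%) of individual intercept variance absorbed by the
    animal-specific allocation terms: 100 (1 - sum_b / sum_a)."""
    if sum_model_a <= 0 or sum_model_b <= 0:
        raise ValueError("variance sums must be positive")
    return float(100.0 * (1.0 - sum_model_b / sum_model_a))


def derived_draws(
    samples: PosteriorSamples, spec: ModelSpec, h2_at: tuple = ()
) -> dict:
    """Draw-wise derived genetic parameters from packed posterior draws.

    Returns name -> array over merged draws: intercept heritability, slope
    ratios, genetic correlations and, for each (term, x) pair in ``h2_at``,
    the conditional heritability and variances at x.
    """
    m = samples.merged()
    names = samples.names
    eff = spec.effect_names

    def col(nm):
        return m[:, names.index(nm)]

    def g0(i, j):
        i, j = sorted((i, j))
        return col(f"G0[{eff[i]},{eff[j]}]")

    def p0(i, j):
        i, j = sorted((i, j))
        return col(f"P0[{eff[i]},{eff[j]}]")

    out = {}
    denom = g0(0, 0) + p0(0, 0) + col("var_pen") + col("var_e")
    out["h2_rfi"] = g0(0, 0) / denom
    for t in spec.animal_terms:
        j = 1 + spec.animal_terms.index(t)
        out[f"slope_ratio_{t}"] = g0(j, j) / (g0(j, j) + p0(j, j))
    k = spec.k
    for i in range(k):
        for j in range(i + 1, k):
            out[f"r_g[{eff[i]},{eff[j]}]"] = g0(i, j) / np.sqrt(g0(i, i) * g0(j, j))
    for term, x in h2_at:
        j = 1 + spec.animal_terms.index(term)
        va = g0(0, 0) + 2 * x * g0(0, j) + x * x * g0(j, j)
        vperm = p0(0, 0) + 2 * x * p0(0, j) + x * x * p0(j, j)
        vp = va + vperm + col("var_pen") + col("var_e")
        tag = f"{term}@{x:+g}"
        out[f"h2[{tag}]"] = va / vp
        out[f"var_a[{tag}]"] = va
        out[f"var_p[{tag}]"] = vp
    return out


def posterior_genetic_summary(
    samples: PosteriorSamples,
    spec: ModelSpec,
    h2_at: tuple = (("mw", -0.75), ("mw", -0.5), ("mw", 0.5), ("mw", 0.75)),
) -> pd.DataFrame:
    """Summary table of the derived genetic parameters (mean, median, sd,
    95% HPD, Pr(>0), ESS), computed draw-wise and then summarized."""
    return summarize_posterior(derived_draws(samples, spec, h2_at=h2_at))
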