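"""Random-regression model specifications and design systems.

Weekly feed intake y_{ijkl} (animal i, week j, batch k, pen l) is modelled
with a batch-by-week class mean, fixed within-week regressions on the
standardized covariates MW, WG and FG, a random pen effect, random
batch-by-week regressions on the same covariates, and animal-specific
additive-genetic and permanent-environmental terms.

Eight nested models differ only in which covariates receive animal-specific
random slopes: model 1 has intercepts only (the classical residual-feed-
intake model), model 8 has slopes on all of MW, WG and FG.  Per animal the
effect vector is (intercept, slopes...), of dimension k = 1 + #slopes, with
covariance G0 (x) A across animals for the genetic part and P0 (x) I for the
permanent part; pen, batch-week regression and residual effects are i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .pedigree import PedigreeTable, relationship_inverse

TERMS = ("mw", "wg", "fg")

MODEL_TERMS = {
    1: (),
    2: ("mw",),
    3: ("wg",),
    4: ("fg",),
    5: ("mw", "wg"),
    6: ("mw", "fg"),
    7: ("wg", "fg"),
    8: ("mw", "wg", "fg"),
}

__all__ = [
    "TERMS",
    "MODEL_TERMS",
    "ModelSpec",
    "VarianceComponents",
    "EffectSet",
    "DesignSystem",
    "model_from_code",
    "build_design_system",
    "assemble_record_mean",
    "predicted_mean",
]


@dataclass(frozen=True)
class ModelSpec:
    """One of the eight nested random-regression models."""

    code: int
    animal_terms: tuple  # subset of TERMS receiving animal-specific slopes

    @property
    def k(self) -> int:
        return 1 + len(self.animal_terms)

    @property
    def effect_names(self) -> tuple:
        return ("int",) + self.animal_terms

    def term_columns(self) -> np.ndarray:
        """Indices into the (mw, wg, fg) covariate block for the slopes."""
        return np.array([TERMS.index(t) for t in self.animal_terms], dtype=np.int64)


def model_from_code(code: int) -> ModelSpec:
    if code not in MODEL_TERMS:
        raise ValueError(f"model code must be 1..8, got {code}")
    return ModelSpec(code=code, animal_terms=MODEL_TERMS[code])


@dataclass
class VarianceComponents:
    """Variance components of one model.

    G0 and P0 are k x k over (intercept, slopes in spec order); the
    intercept entries are on the (g/d)^2 scale and slope entries on
    (g/d per covariate sd unit)^2. var_gamma holds one batch-week
    regression variance per covariate actually fitted.
    """

    spec: ModelSpec
    G0: np.ndarray
    P0: np.ndarray
    var_pen: float
    var_e: float
    var_gamma: dict = field(default_factory=dict)  # term -> variance

    def __post_init__(self):
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        k = self.spec.k
        if self.G0.shape != (k, k) or self.P0.shape != (k, k):
            raise ValueError(f"G0/P0 must be {k}x{k} for model {self.spec.code}")

    def validate_pd(self) -> None:
        for name, m in (("G0", self.G0), ("P0", self.P0)):
            np.linalg.cholesky(m)  # raises LinAlgError if not PD
        if self.var_pen <= 0 or self.var_e <= 0:
            raise ValueError("scalar variances must be positive")

    def subset(self, spec: ModelSpec) -> "VarianceComponents":
        """Re-dimension a richer component set to a nested model's terms."""
        if not set(spec.animal_terms) <= set(self.spec.animal_terms):
            raise ValueError("target spec is not nested in source spec")
        idx = [0] + [1 + self.spec.animal_terms.index(t) for t in spec.animal_terms]
        idx = np.array(idx)
        return VarianceComponents(
            spec=spec,
            G0=self.G0[np.ix_(idx, idx)],
            P0=self.P0[np.ix_(idx, idx)],
            var_pen=self.var_pen,
            var_e=self.var_e,
            var_gamma=dict(self.var_gamma),
        )

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            spec=self.spec,
            G0=self.G0.copy(),
            P0=self.P0.copy(),
            var_pen=self.var_pen,
            var_e=self.var_e,
            var_gamma=dict(self.var_gamma),
        )


@dataclass
class EffectSet:
    """All location effects of a design system, in model order."""

    ba: np.ndarray        # (n_ba,)
    beta: np.ndarray      # (n_week, 3) fixed regressions on mw, wg, fg
    pen: np.ndarray       # (n_pen,)
    gamma: np.ndarray     # (n_ba, 3) batch-week random regressions
    a: np.ndarray         # (n_ped, k) genetic
    p: np.ndarray         # (n_rec_animals, k) permanent environmental

    @classmethod
    def zeros(cls, system: "DesignSystem") -> "EffectSet":
        k = system.spec.k
        return cls(
            ba=np.zeros(system.n_ba),
            beta=np.zeros((system.n_week, 3)),
            pen=np.zeros(system.n_pen),
            gamma=np.zeros((system.n_ba, 3)),
            a=np.zeros((system.n_ped, k)),
            p=np.zeros((system.n_rec_animals, k)),
        )


@dataclass
class DesignSystem:
    """Fully indexed design for one model on prepared weekly records."""

    spec: ModelSpec
    y: np.ndarray                 # (n,) feed intake, g/d
    x: np.ndarray                 # (n, 3) standardized mw, wg, fg
    z: np.ndarray                 # (n, k) animal design: [1, selected covariates]
    ba_idx: np.ndarray            # (n,) batch-week class index
    week_idx: np.ndarray          # (n,) week level for nested fixed regressions
    pen_idx: np.ndarray           # (n,)
    anim_idx: np.ndarray          # (n,) pedigree position of the record's animal
    rec_idx: np.ndarray           # (n,) index into recorded-animal list (permanent)
    rec_animals: np.ndarray       # pedigree positions of animals with records
    ainv: sparse.csr_matrix       # pedigree relationship inverse (n_ped x n_ped)
    pedigree: PedigreeTable
    with_gamma: bool = True
    with_fixed_reg: bool = True
    ba_labels: list = field(default_factory=list)
    week_labels: list = field(default_factory=list)
    pen_labels: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_ba(self) -> int:
        return len(self.ba_labels)

    @property
    def n_week(self) -> int:
        return len(self.week_labels)

    @property
    def n_pen(self) -> int:
        return len(self.pen_labels)

    @property
    def n_ped(self) -> int:
        return self.ainv.shape[0]

    @property
    def n_rec_animals(self) -> int:
        return self.rec_animals.size


def _codes(values) -> tuple:
    labels, idx = np.unique(np.asarray(values), return_inverse=True)
    return list(labels), idx.astype(np.int64)


def build_design_system(
    records: pd.DataFrame,
    ped: PedigreeTable,
    spec: ModelSpec,
    with_gamma: bool = True,
    nest_by_week: bool = True,
    with_fixed_reg: bool = True,
    ainv: sparse.csr_matrix | None = None,
) -> DesignSystem:
    """Wire prepared weekly records and a pedigree into a model design.

    ``records`` must carry animal_id, batch, pen, week, fi and standardized
    mw, wg, fg. ``nest_by_week=False`` collapses the fixed regressions to a
    single global coefficient per covariate and ``with_gamma=False`` drops
    the batch-week random regressions (both used by the selection
    simulator, whose generating process has no batch or age structure).
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    unknown = set(records["animal_id"]) - set(ped.ids.tolist())
    if unknown:
        raise ValueError(f"records reference animals absent from pedigree: {sorted(unknown)[:5]}")

    y = records["fi"].to_numpy(float)
    x = records[["mw", "wg", "fg"]].to_numpy(float)

    ba_key = list(zip(records["batch"].tolist(), records["week"].tolist()))
    ba_labels, ba_idx = _codes([f"{b}|{w}" for b, w in ba_key])
    if nest_by_week:
        week_labels, week_idx = _codes(records["week"])
    else:
        week_labels, week_idx = ["all"], np.zeros(len(records), dtype=np.int64)
    pen_labels, pen_idx = _codes(records["pen"])

    anim_idx = ped.positions(records["animal_id"])
    rec_animals = np.unique(anim_idx)
    rec_pos = {a: i for i, a in enumerate(rec_animals)}
    rec_idx = np.array([rec_pos[a] for a in anim_idx], dtype=np.int64)

    cols = spec.term_columns()
    z = np.column_stack([np.ones(len(records))] + [x[:, c] for c in cols])

    if ainv is None:
        ainv = relationship_inverse(ped).a_inverse

    return DesignSystem(
        spec=spec,
        y=y,
        x=x,
        z=z,
        ba_idx=ba_idx,
        week_idx=week_idx,
        pen_idx=pen_idx,
        anim_idx=anim_idx,
        rec_idx=rec_idx,
        rec_animals=rec_animals,
        ainv=ainv,
        pedigree=ped,
        with_gamma=with_gamma,
        with_fixed_reg=with_fixed_reg,
        ba_labels=ba_labels,
        week_labels=week_labels,
        pen_labels=pen_labels,
    )


def predicted_mean(system: DesignSystem, eff: EffectSet) -> np.ndarray:
    """Fitted conditional mean of every record given all location effects."""
    mu = eff.ba[system.ba_idx].copy()
    if system.with_fixed_reg:
        mu += np.sum(system.x * eff.beta[system.week_idx], axis=1)
    mu += eff.pen[system.pen_idx]
    if system.with_gamma:
        mu += np.sum(system.x * eff.gamma[system.ba_idx], axis=1)
    mu += np.sum(system.z * eff.a[system.anim_idx], axis=1)
    mu += np.sum(system.z * eff.p[system.rec_idx], axis=1)
    return mu


def assemble_record_mean(system: DesignSystem, eff: EffectSet, r: int) -> float:
    """Expected feed intake of record ``r``: explicit term-by-term sum."""
    total = eff.ba[system.ba_idx[r]]
    if system.with_fixed_reg:
        for c in range(3):
            total += system.x[r, c] * eff.beta[system.week_idx[r], c]
    total += eff.pen[system.pen_idx[r]]
    if system.with_gamma:
        for c in range(3):
            total += system.x[r, c] * eff.gamma[system.ba_idx[r], c]
    for j in range(system.spec.k):
        total += system.z[r, j] * eff.a[system.anim_idx[r], j]
        total += system.z[r, j] * eff.p[system.rec_idx[r], j]
    return float(total)
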