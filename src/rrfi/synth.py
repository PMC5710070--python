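"""Synthetic observational datasets with known generating parameters.

Two tracks serve different test depths:

* ``generate_weekly_dataset`` draws weekly standardized covariates (MW,
  WG, FG) from the multi-trait pen + additive + permanent + weekly-residual
  structure and feed intake from the full animal-specific random-regression
  model with batch-by-week means, week-nested fixed regressions and
  batch-week random regressions. It returns analysis-ready weekly records
  plus every latent effect, and is the fixture for parameter-recovery
  studies.

* ``generate_observational_dataset`` additionally emits the raw files the
  preparation pipeline consumes: daily feed intake with missing days,
  sparse body-weight/backfat measurement events and a batch/pen map.
  Growth curves are exact quadratics per animal, so the three-coefficient
  Legendre interpolation in the preparation step reproduces them exactly,
  and daily intake is the weekly value plus day noise re-centred within
  the week, so weekly means round-trip exactly when no days are missing.

Default fixed regressions per week and batch-week intake means follow the
published weekly coefficient and intake profiles of the source population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import VarianceComponents, model_from_code
from .pedigree import PedigreeTable, validate_and_sort_pedigree
from .simulate import TrueParams, default_true_params, _mvn

__all__ = [
    "FixtureConfig",
    "SyntheticDataset",
    "generate_weekly_dataset",
    "generate_observational_dataset",
    "write_fixture_files",
    "read_fixture_files",
]

WEEKS = np.arange(15, 26)
# weekly fixed regression means of feed intake on standardized MW/WG/FG (g/d per sd)
BETA_BY_WEEK = np.array([
    [295, 13, 16], [286, 2, 36], [284, 8, 24], [266, 13, 37], [272, 49, 24],
    [220, 57, 37], [210, 96, 38], [205, 101, 24], [192, 102, 56],
    [193, 120, 23], [157, 146, 49],
], dtype=float)
# weekly mean daily intake, g/d
FI_BY_WEEK = np.array(
    [2220, 2390, 2510, 2690, 2850, 2910, 2980, 3030, 3100, 3040, 3070],
    dtype=float,
)


@dataclass
class FixtureConfig:
    n_batches: int = 2
    animals_per_batch: int = 160
    pen_size: int = 10
    week_min: int = 15
    week_max: int = 25
    missing_day_frac: float = 0.1
    measurements_per_animal: tuple = (4, 11)
    day_noise_sd: float = 50.0
    offspring_per_dam: int = 4
    dams_per_sire: int = 4
    params: TrueParams | None = None
    seed: int = 0

    def __post_init__(self):
        if not (15 <= self.week_min <= self.week_max <= 25):
            raise ValueError("weeks must lie within 15..25")
        if not 0 <= self.missing_day_frac < 1:
            raise ValueError("missing_day_frac must be in [0, 1)")
        if self.params is None:
            self.params = default_true_params()

    @property
    def weeks(self) -> np.ndarray:
        return np.arange(self.week_min, self.week_max + 1)


@dataclass
class SyntheticDataset:
    config: FixtureConfig
    pedigree: PedigreeTable
    records: pd.DataFrame                  # weekly standardized records
    truth: dict
    daily: pd.DataFrame | None = None      # raw daily intake (observational track)
    events: pd.DataFrame | None = None     # raw measurement events
    penmap: pd.DataFrame | None = None


def _fixture_pedigree(config: FixtureConfig) -> tuple:
    """Founder sires/dams plus recorded offspring in paternal half-sib
    families (``offspring_per_dam`` full sibs per dam, ``dams_per_sire``
    dams per sire), per batch."""
    opd, dps = config.offspring_per_dam, config.dams_per_sire
    rows = []
    next_id = 1
    offspring = []
    for b in range(config.n_batches):
        n_off = config.animals_per_batch
        n_dams = int(np.ceil(n_off / opd))
        n_sires = int(np.ceil(n_dams / dps))
        sires = list(range(next_id, next_id + n_sires))
        next_id += n_sires
        dams = list(range(next_id, next_id + n_dams))
        next_id += n_dams
        for s in sires:
            rows.append((s, 0, 0))
        for d in dams:
            rows.append((d, 0, 0))
        for i in range(n_off):
            d = dams[i // opd % n_dams]
            s = sires[(i // opd) // dps % n_sires]
            rows.append((next_id, s, d))
            offspring.append((next_id, b))
            next_id += 1
    ped = validate_and_sort_pedigree(rows)
    return ped, offspring


def _pedigree_additive_draws(ped: PedigreeTable, cov: np.ndarray, rng) -> np.ndarray:
    """Breeding values over a pedigree: founders from N(0, cov), offspring
    mid-parent plus Mendelian sampling with half the founder covariance."""
    k = cov.shape[0]
    chol = np.linalg.cholesky(cov)
    chol_half = np.linalg.cholesky(0.5 * cov)
    a = np.empty((ped.n, k))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = chol @ rng.standard_normal(k)
        else:
            mid = 0.5 * (a[s] if s >= 0 else 0.0) + 0.5 * (a[d] if d >= 0 else 0.0)
            a[i] = mid + chol_half @ rng.standard_normal(k)
    return a


def _standardize_cells(df: pd.DataFrame, cols) -> pd.DataFrame:
    for c in cols:
        grp = df.groupby(["week", "batch"])[c]
        df[c] = (df[c] - grp.transform("mean")) / grp.transform("std")
    return df


def generate_weekly_dataset(config: FixtureConfig) -> SyntheticDataset:
    """Weekly records straight from the generating model (no raw files)."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    params = config.params
    vc = params.fi_components
    cp = params.covariate_params
    ped, offspring = _fixture_pedigree(config)

    a_fi = _pedigree_additive_draws(ped, vc.G0, rng)
    a_cov = _pedigree_additive_draws(ped, cp.G_t, rng)
    off_ids = [o for o, _ in offspring]
    off_pos = ped.positions(off_ids)
    n_off = len(off_ids)
    p_fi = _mvn(rng, vc.P0, n_off)
    p_cov = _mvn(rng, cp.P_t, n_off)

    batch = np.array([b for _, b in offspring])
    pen = np.empty(n_off, dtype=np.int64)
    pen_counter = 0
    pen_fi = {}
    pen_cov = {}
    for b in range(config.n_batches):
        members = np.where(batch == b)[0]
        members = members[rng.permutation(members.size)]
        for start in range(0, members.size, config.pen_size):
            pen_fi[pen_counter] = rng.normal(0, np.sqrt(vc.var_pen))
            pen_cov[pen_counter] = _mvn(rng, cp.B_t)
            pen[members[start: start + config.pen_size]] = pen_counter
            pen_counter += 1

    weeks = config.weeks
    wsel = np.searchsorted(WEEKS, weeks)
    beta = BETA_BY_WEEK[wsel]
    ba_mean = {}
    gamma = {}
    for b in range(config.n_batches):
        shift = rng.normal(0, 50.0)
        for wi, w in enumerate(weeks):
            ba_mean[(b, w)] = FI_BY_WEEK[wsel[wi]] + shift + rng.normal(0, 30.0)
            gamma[(b, w)] = np.array([
                rng.normal(0, np.sqrt(vc.var_gamma[t])) for t in ("mw", "wg", "fg")
            ])

    rows = []
    for i in range(n_off):
        base_cov = a_cov[off_pos[i]] + p_cov[i] + pen_cov[pen[i]]
        for wi, w in enumerate(weeks):
            x = base_cov + _mvn(rng, cp.R_t)
            rows.append((off_ids[i], batch[i], int(pen[i]), int(w), wi,
                         x[0], x[1], x[2]))
    df = pd.DataFrame(
        rows, columns=["animal_id", "batch", "pen", "week", "wi", "mw", "wg", "fg"]
    )
    df = _standardize_cells(df, ("mw", "wg", "fg"))

    x = df[["mw", "wg", "fg"]].to_numpy()
    wi = df["wi"].to_numpy()
    pos = ped.positions(df["animal_id"])
    rec_off = np.searchsorted(off_pos, pos)  # off_pos sorted by construction
    z = np.column_stack([np.ones(len(df)), x])
    fi = (
        np.array([ba_mean[(b, w)] for b, w in zip(df["batch"], df["week"])])
        + np.sum(x * beta[wi], axis=1)
        + np.array([pen_fi[p] for p in df["pen"]])
        + np.sum(x * np.array([gamma[(b, w)] for b, w in
                               zip(df["batch"], df["week"])]), axis=1)
        + np.sum(z * a_fi[pos], axis=1)
        + np.sum(z * p_fi[rec_off], axis=1)
        + rng.normal(0, np.sqrt(vc.var_e), len(df))
    )
    df["fi"] = fi
    df = df.drop(columns="wi")

    truth = {
        "G0": vc.G0.tolist(), "P0": vc.P0.tolist(),
        "var_pen": vc.var_pen, "var_e": vc.var_e,
        "var_gamma": dict(vc.var_gamma),
        "beta_by_week": beta.tolist(),
        "a_fi": a_fi.tolist(), "p_fi": p_fi.tolist(),
        "offspring_ids": off_ids,
        "seed": config.seed,
    }
    return SyntheticDataset(config=config, pedigree=ped, records=df, truth=truth)


def generate_observational_dataset(config: FixtureConfig) -> SyntheticDataset:
    """Raw-file fixture: quadratic growth curves, sparse measurement events,
    daily intake with missingness, plus the implied weekly records."""
    from . import phenoprep

    rng = np.random.Generator(np.random.PCG64(config.seed))
    params = config.params
    vc = params.fi_components
    ped, offspring = _fixture_pedigree(config)
    off_ids = [o for o, _ in offspring]
    off_pos = ped.positions(off_ids)
    n_off = len(off_ids)

    a_fi = _pedigree_additive_draws(ped, vc.G0, rng)
    p_fi = _mvn(rng, vc.P0, n_off)
    batch = np.array([b for _, b in offspring])

    pen = np.empty(n_off, dtype=np.int64)
    pen_counter = 0
    pen_fi = {}
    for b in range(config.n_batches):
        members = np.where(batch == b)[0]
        members = members[rng.permutation(members.size)]
        for start in range(0, members.size, config.pen_size):
            pen_fi[pen_counter] = rng.normal(0, np.sqrt(vc.var_pen))
            pen[members[start: start + config.pen_size]] = pen_counter
            pen_counter += 1

    # exact quadratic growth curves per animal (kg, mm vs day of age)
    t0 = 105.0
    w0 = rng.normal(51.0, 6.0, n_off)
    ws = rng.normal(0.85, 0.10, n_off)
    wc = rng.normal(0.0006, 0.0004, n_off)
    f0 = rng.normal(9.5, 1.2, n_off)
    fs = rng.normal(0.12, 0.025, n_off)
    fc = rng.normal(0.0004, 0.0002, n_off)

    def bw(i, t):
        return w0[i] + ws[i] * (t - t0) + wc[i] * (t - t0) ** 2

    def bf(i, t):
        return f0[i] + fs[i] * (t - t0) + fc[i] * (t - t0) ** 2

    lo_meas, hi_meas = config.measurements_per_animal
    ev_rows = []
    for i in range(n_off):
        n_meas = int(rng.integers(lo_meas, hi_meas + 1))
        ages = np.linspace(100, 184, n_meas) + rng.uniform(-2, 2, n_meas)
        ages[0] = min(ages[0], 7.0 * config.week_min)
        ages[-1] = max(ages[-1], 7.0 * (config.week_max + 1))
        for t in np.round(ages, 1):
            ev_rows.append((off_ids[i], t, bw(i, t), bf(i, t)))
    events = pd.DataFrame(
        ev_rows, columns=["animal_id", "age_days", "body_weight", "backfat"]
    )

    # weekly raw covariates exactly as the preparation step will derive them
    weeks = config.weeks
    rows = []
    for i in range(n_off):
        for w in weeks:
            d0, d1 = 7.0 * w, 7.0 * (w + 1)
            mw_raw = (0.5 * (bw(i, d0) + bw(i, d1))) ** 0.75
            wg_raw = (bw(i, d1) - bw(i, d0)) / 7.0
            fg_raw = (bf(i, d1) - bf(i, d0)) / 7.0
            rows.append((off_ids[i], batch[i], int(pen[i]), int(w),
                         mw_raw, wg_raw, fg_raw))
    df = pd.DataFrame(rows, columns=[
        "animal_id", "batch", "pen", "week", "mw_raw", "wg_raw", "fg_raw"])
    for c in ("mw", "wg", "fg"):
        grp = df.groupby(["week", "batch"])[f"{c}_raw"]
        df[c] = (df[c + "_raw"] - grp.transform("mean")) / grp.transform("std")

    wsel = np.searchsorted(WEEKS, df["week"].to_numpy())
    beta = BETA_BY_WEEK[wsel]
    x = df[["mw", "wg", "fg"]].to_numpy()
    z = np.column_stack([np.ones(len(df)), x])
    pos = ped.positions(df["animal_id"])
    rec_off = np.searchsorted(off_pos, pos)
    ba_shift = {b: rng.normal(0, 50.0) for b in range(config.n_batches)}
    gamma = {
        (b, int(w)): np.array([rng.normal(0, np.sqrt(vc.var_gamma[t]))
                               for t in ("mw", "wg", "fg")])
        for b in range(config.n_batches) for w in weeks
    }
    df["fi"] = (
        FI_BY_WEEK[wsel]
        + np.array([ba_shift[b] for b in df["batch"]])
        + np.sum(x * beta, axis=1)
        + np.array([pen_fi[p] for p in df["pen"]])
        + np.sum(x * np.array([gamma[(b, w)] for b, w in
                               zip(df["batch"], df["week"])]), axis=1)
        + np.sum(z * a_fi[pos], axis=1)
        + np.sum(z * p_fi[rec_off], axis=1)
        + rng.normal(0, np.sqrt(vc.var_e), len(df))
    )

    # daily disaggregation: weekly value + day noise re-centred to preserve
    # the weekly mean exactly; then knock out missing days
    d_rows = []
    for row in df.itertuples(index=False):
        days = 7 * row.week + np.arange(7)
        noise = rng.normal(0, config.day_noise_sd, 7)
        noise -= noise.mean()
        vals = row.fi + noise
        miss = rng.random(7) < config.missing_day_frac
        if miss.sum() >= 6:
            miss[:] = False  # keep the animal-week identifiable
        for d, v, m in zip(days, vals, miss):
            d_rows.append((row.animal_id, int(d), np.nan if m else v))
    daily = pd.DataFrame(d_rows, columns=["animal_id", "age_days", "intake"])
    penmap = pd.DataFrame({
        "animal_id": off_ids, "batch": batch, "pen": pen,
    })

    truth = {
        "G0": vc.G0.tolist(), "P0": vc.P0.tolist(),
        "var_pen": vc.var_pen, "var_e": vc.var_e,
        "var_gamma": dict(vc.var_gamma),
        "a_fi": a_fi.tolist(), "p_fi": p_fi.tolist(),
        "offspring_ids": off_ids,
        "seed": config.seed,
    }
    return SyntheticDataset(
        config=config, pedigree=ped, records=df, truth=truth,
        daily=daily, events=events, penmap=penmap,
    )


def write_fixture_files(ds: SyntheticDataset, directory) -> dict:
    """Write the dataset as delimited text files; byte-deterministic given
    the same dataset. Returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    ped = ds.pedigree
    ped_df = pd.DataFrame({
        "animal": ped.ids,
        "sire": [ped.ids[s] if s >= 0 else 0 for s in ped.sire],
        "dam": [ped.ids[dd] if dd >= 0 else 0 for dd in ped.dam],
    })
    paths["pedigree"] = d / "pedigree.csv"
    ped_df.to_csv(paths["pedigree"], index=False)

    paths["weekly"] = d / "weekly_records.csv"
    ds.records.to_csv(paths["weekly"], index=False, float_format="%.10g")
    for name, df in (("daily_intake", ds.daily), ("measurements", ds.events),
                     ("penmap", ds.penmap)):
        if df is not None:
            paths[name] = d / f"{name}.csv"
            df.to_csv(paths[name], index=False, float_format="%.10g")
    paths["truth"] = d / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return paths


def read_fixture_files(directory) -> dict:
    """Read back the tables written by ``write_fixture_files``."""
    d = Path(directory)
    out = {"pedigree": pd.read_csv(d / "pedigree.csv")}
    for name, fn in (("weekly", "weekly_records.csv"),
                     ("daily_intake", "daily_intake.csv"),
                     ("measurements", "measurements.csv"),
                     ("penmap", "penmap.csv")):
        p = d / fn
        if p.exists():
            out[name] = pd.read_csv(p)
    tp = d / "truth.json"
    if tp.exists():
        out["truth"] = json.loads(tp.read_text())
    return out
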