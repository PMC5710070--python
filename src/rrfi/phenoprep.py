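"""Weekly feed-efficiency records from raw daily intake and measurement events.

Raw inputs are daily feed intake (g/d, with missing days), sparse body-weight
(kg) and backfat (mm) measurement events, and a batch/pen map. The pipeline:

1. fill missing daily intake from an animal-nested three-coefficient
   Legendre polynomial fitted to the animal's observed days;
2. interpolate body weight and backfat to the first and last day of each
   age-week with the same animal-nested Legendre trajectory;
3. derive weekly records: FI = weekly mean intake, WG and FG = endpoint
   gains / 7 d, MW = (mean weekly body weight)^0.75;
4. keep weeks 15-25 and animals housed in sufficiently large pens;
5. standardize MW/WG/FG to mean 0, sd 1 within each week-by-batch cell.

Weeks are age-weeks: week ``w`` spans days ``7w`` to ``7w+6``; the "first
and last day" endpoints used for gains are days ``7w`` and ``7(w+1)`` so that
(end - start)/7 is the exact average daily gain of the week.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Legendre

__all__ = [
    "WEEK_MIN",
    "WEEK_MAX",
    "fit_animal_trajectory",
    "impute_daily_intake",
    "interpolate_weight_backfat",
    "derive_weekly_covariates",
    "apply_filters",
    "standardize_within_cell",
    "prepare_weekly_records",
]

WEEK_MIN = 15
WEEK_MAX = 25
MW_EXPONENT = 0.75


class PrepError(ValueError):
    pass


def fit_animal_trajectory(ages, values, n_coef: int = 3) -> Legendre:
    """Least-squares Legendre polynomial (orders 0..n_coef-1) for one animal.

    Ages are rescaled to [-1, 1] over the animal's own observed age range
    (the fit is animal-nested). Returns a callable trajectory; evaluation
    outside the observed range is not meaningful and callers restrict to it.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    distinct = np.unique(ages)
    if distinct.size < n_coef:
        raise PrepError(
            f"need >= {n_coef} distinct ages to fit a trajectory, got {distinct.size}"
        )
    if distinct.size == ages.size and ages.size == n_coef:
        # exact interpolation; lstsq handles it too, but keep it well-posed
        pass
    return Legendre.fit(ages, values, deg=n_coef - 1)


def impute_daily_intake(daily: pd.DataFrame, n_coef: int = 3) -> pd.DataFrame:
    """Fill missing daily intake by each animal's Legendre trajectory.

    ``daily`` columns: animal_id, age_days, intake (NaN = missing meal-level
    validation). Observed values are never altered. Animals whose observed
    days cannot support the fit are dropped with a warning column-free
    (callers can diff animal sets).
    """
    out = []
    for animal, grp in daily.groupby("animal_id", sort=False):
        obs = grp.dropna(subset=["intake"])
        if obs["age_days"].nunique() < n_coef:
            continue  # all-missing or too sparse: excluded
        if grp["intake"].isna().any():
            traj = fit_animal_trajectory(obs["age_days"], obs["intake"], n_coef)
            g = grp.copy()
            miss = g["intake"].isna()
            g.loc[miss, "intake"] = traj(g.loc[miss, "age_days"].to_numpy(float))
            out.append(g)
        else:
            out.append(grp)
    if not out:
        return daily.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def interpolate_weight_backfat(events: pd.DataFrame, n_coef: int = 3) -> pd.DataFrame:
    """Per-week first/last-day body weight and backfat from sparse events.

    ``events`` columns: animal_id, age_days, body_weight, backfat. For each
    animal a Legendre trajectory is fitted per trait and evaluated at days
    7w and 7(w+1) for every age-week fully inside the measured range.
    Returns columns: animal_id, week, bw_start, bw_end, bf_start, bf_end.
    """
    rows = []
    for animal, grp in events.groupby("animal_id", sort=False):
        ages = grp["age_days"].to_numpy(float)
        if np.unique(ages).size < n_coef:
            raise PrepError(f"animal {animal!r}: fewer than {n_coef} measurement ages")
        bw = fit_animal_trajectory(ages, grp["body_weight"], n_coef)
        bf = fit_animal_trajectory(ages, grp["backfat"], n_coef)
        lo, hi = ages.min(), ages.max()
        w0 = int(np.ceil(lo / 7.0))
        w1 = int(np.floor(hi / 7.0)) - 1  # need day 7(w+1) inside range
        for w in range(w0, w1 + 1):
            d0, d1 = 7.0 * w, 7.0 * (w + 1)
            rows.append(
                (animal, w, bw(d0), bw(d1), bf(d0), bf(d1))
            )
    return pd.DataFrame(
        rows, columns=["animal_id", "week", "bw_start", "bw_end", "bf_start", "bf_end"]
    )


def derive_weekly_covariates(
    daily: pd.DataFrame, weekly_endpoints: pd.DataFrame
) -> pd.DataFrame:
    """Raw weekly records: FI, MW, WG, FG.

    FI is the mean of the week's daily intake; WG and FG are endpoint
    differences over 7 days; MW is the mean of the weekly endpoint weights
    raised to 0.75. Weeks lacking intake days or endpoints are skipped.
    """
    d = daily.copy()
    d["week"] = (d["age_days"] // 7).astype(int)
    fi = (
        d.dropna(subset=["intake"])
        .groupby(["animal_id", "week"], sort=False)["intake"]
        .mean()
        .rename("fi")
        .reset_index()
    )
    out = weekly_endpoints.merge(fi, on=["animal_id", "week"], how="inner")
    out["mw_raw"] = (0.5 * (out["bw_start"] + out["bw_end"])) ** MW_EXPONENT
    out["wg_raw"] = (out["bw_end"] - out["bw_start"]) / 7.0
    out["fg_raw"] = (out["bf_end"] - out["bf_start"]) / 7.0
    return out[["animal_id", "week", "fi", "mw_raw", "wg_raw", "fg_raw"]]


def apply_filters(
    records: pd.DataFrame,
    penmap: pd.DataFrame,
    week_min: int = WEEK_MIN,
    week_max: int = WEEK_MAX,
    min_group_size: int = 8,
) -> pd.DataFrame:
    """Restrict to the analysis window and to adequately grouped pens.

    Keeps weeks in [week_min, week_max] and animals housed with at least
    ``min_group_size - 1`` pen mates (default: group of 8, i.e. the animal
    plus seven or more others). Attaches batch and pen columns.
    """
    rec = records.merge(penmap[["animal_id", "batch", "pen"]], on="animal_id", how="inner")
    rec = rec[(rec["week"] >= week_min) & (rec["week"] <= week_max)]
    sizes = penmap.groupby("pen")["animal_id"].nunique()
    ok_pens = sizes[sizes >= min_group_size].index
    rec = rec[rec["pen"].isin(ok_pens)].reset_index(drop=True)
    return rec


def standardize_within_cell(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize MW/WG/FG to mean 0, sd 1 within each week-by-batch cell.

    Sample sd (divisor n-1). Raw columns are retained; cell means and sds
    are attached so the transform is invertible. Cells with fewer than two
    records or zero spread cannot be standardized and raise.
    """
    rec = records.copy()
    for col in ("mw", "wg", "fg"):
        raw = f"{col}_raw"
        grp = rec.groupby(["week", "batch"])[raw]
        n = grp.transform("size")
        if (n < 2).any():
            bad = rec.loc[n < 2, ["week", "batch"]].iloc[0]
            raise PrepError(
                f"cannot standardize {raw}: cell week={bad['week']} "
                f"batch={bad['batch']} has fewer than 2 records"
            )
        mu = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1
        if (sd <= 0).any():
            bad = rec.loc[sd <= 0, ["week", "batch"]].iloc[0]
            raise PrepError(
                f"cannot standardize {raw}: zero spread in cell "
                f"week={bad['week']} batch={bad['batch']}"
            )
        rec[col] = (rec[raw] - mu) / sd
        rec[f"{col}_cell_mean"] = mu
        rec[f"{col}_cell_sd"] = sd
    return rec


def prepare_weekly_records(
    daily: pd.DataFrame,
    events: pd.DataFrame,
    penmap: pd.DataFrame,
    week_min: int = WEEK_MIN,
    week_max: int = WEEK_MAX,
    min_group_size: int = 8,
) -> pd.DataFrame:
    """Full preparation pipeline: raw tables -> standardized weekly records."""
    filled = impute_daily_intake(daily)
    endpoints = interpolate_weight_backfat(events)
    weekly = derive_weekly_covariates(filled, endpoints)
    filtered = apply_filters(weekly, penmap, week_min, week_max, min_group_size)
    return standardize_within_cell(filtered)
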