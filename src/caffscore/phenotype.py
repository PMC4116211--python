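"""Harmonization of raw questionnaire beverage records into daily caffeine exposure.

Coffee and tea are reported as drinks per day, separately for weekdays and
weekend days; cola as drinks per week, either as an open numeric count or as a
closed frequency category. This module converts every stream to drinks/day,
masks implausible daily values, and combines the three caffeinated streams
into a single caffeine-content-weighted exposure in mg/day:

    total = 75 * coffee + 40 * tea + 34.5 * cola     [mg/day]

Decaffeinated streams are harmonized identically but never enter the total;
they serve as negative-control phenotypes downstream.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .constants import (
    BEVERAGES,
    CAFFEINE_MG_PER_DRINK,
    CLOSED_RECODE,
    OBSERVATION_FORMATS,
    OUTLIER_MAX_PER_DAY,
    TIME_POINTS,
)

#: Long-format observation table schema (one row per questionnaire answer).
OBSERVATION_COLUMNS = [
    "subject_id",
    "time_point",
    "beverage",
    "caffeinated",
    "format",
    "weekday_count",
    "weekend_count",
    "weekly_value",
    "closed_category",
]

#: Wide-format phenotype table columns, one row per subject x time point.
PHENOTYPE_COLUMNS = [
    "subject_id",
    "time_point",
    "coffee_per_day",
    "tea_per_day",
    "cola_per_day",
    "total_caffeine_mg",
    "decaf_coffee_per_day",
    "decaf_tea_per_day",
    "decaf_cola_per_day",
]


def _is_null(x: Any) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def recode_closed_response(category: str) -> float:
    """Map a closed-format frequency label to drinks per week.

    Raises ValueError on an unrecognized label (a schema mismatch should be
    loud, not silently missing).
    """
    try:
        return CLOSED_RECODE[category]
    except KeyError:
        raise ValueError(
            f"unknown closed-format category {category!r}; "
            f"expected one of {list(CLOSED_RECODE)}"
        ) from None


def combine_weekday_weekend(weekday_count: float | None, weekend_count: float | None) -> float | None:
    """Day-weighted mean of weekday and weekend-day counts: (5*wd + 2*we) / 7.

    Returns None if either input is missing.
    """
    if _is_null(weekday_count) or _is_null(weekend_count):
        return None
    if weekday_count < 0 or weekend_count < 0:
        raise ValueError(
            f"negative drink count: weekday={weekday_count}, weekend={weekend_count}"
        )
    return (5.0 * weekday_count + 2.0 * weekend_count) / 7.0


def weekly_to_daily(weekly_value: float | None) -> float | None:
    """Convert drinks/week to drinks/day; None passes through."""
    if _is_null(weekly_value):
        return None
    if weekly_value < 0:
        raise ValueError(f"negative weekly count: {weekly_value}")
    return weekly_value / 7.0


def mask_outliers(value: float | None, beverage: str) -> float | None:
    """Set implausible daily values to missing.

    The rule is strict: values at the ceiling (10 coffee / 15 tea / 21 cola
    drinks per day) are retained; values strictly above it become None.
    """
    if beverage not in OUTLIER_MAX_PER_DAY:
        raise ValueError(f"unknown beverage {beverage!r}; expected one of {BEVERAGES}")
    if _is_null(value):
        return None
    if value < 0:
        raise ValueError(f"negative daily value: {value}")
    return None if value > OUTLIER_MAX_PER_DAY[beverage] else value


def total_caffeine(
    coffee_per_day: float | None,
    tea_per_day: float | None,
    cola_per_day: float | None,
) -> float | None:
    """Caffeine-weighted daily total in mg; missing if any component is missing."""
    components = (coffee_per_day, tea_per_day, cola_per_day)
    if any(_is_null(c) for c in components):
        return None
    if any(c < 0 for c in components):
        raise ValueError(f"negative component in {components}")
    return (
        CAFFEINE_MG_PER_DRINK["coffee"] * coffee_per_day
        + CAFFEINE_MG_PER_DRINK["tea"] * tea_per_day
        + CAFFEINE_MG_PER_DRINK["cola"] * cola_per_day
    )


def _validate_observations(obs: pd.DataFrame) -> None:
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    bad_bev = set(obs["beverage"].dropna().unique()) - set(BEVERAGES)
    if bad_bev:
        raise ValueError(f"unknown beverages {sorted(bad_bev)}; expected {BEVERAGES}")
    bad_tp = set(obs["time_point"].dropna().unique()) - set(TIME_POINTS)
    if bad_tp:
        raise ValueError(f"unknown time points {sorted(bad_tp)}; expected {TIME_POINTS}")
    bad_fmt = set(obs["format"].dropna().unique()) - set(OBSERVATION_FORMATS)
    if bad_fmt:
        raise ValueError(f"unknown formats {sorted(bad_fmt)}; expected {OBSERVATION_FORMATS}")
    key = ["subject_id", "time_point", "beverage", "caffeinated"]
    dup = obs.duplicated(subset=key, keep=False)
    if dup.any():
        keys = obs.loc[dup, key].drop_duplicates().head(10).to_records(index=False).tolist()
        raise ValueError(f"duplicate observation keys (first 10 shown): {keys}")
    for col in ("weekday_count", "weekend_count", "weekly_value"):
        vals = pd.to_numeric(obs[col], errors="coerce")
        if (vals < 0).any():
            bad = obs.loc[vals < 0, ["subject_id", "time_point", "beverage", col]]
            raise ValueError(f"negative counts in column {col}:\n{bad.head(10)}")


def _daily_values(obs: pd.DataFrame) -> pd.Series:
    """Vectorized format conversion to drinks/day (no outlier masking yet)."""
    fmt = obs["format"]
    wd = pd.to_numeric(obs["weekday_count"], errors="coerce")
    we = pd.to_numeric(obs["weekend_count"], errors="coerce")
    weekly = pd.to_numeric(obs["weekly_value"], errors="coerce")

    closed = obs["closed_category"]
    is_closed = fmt == "weekly_closed"
    known = closed.isin(CLOSED_RECODE) | closed.isna()
    if (is_closed & ~known).any():
        bad = sorted(closed[is_closed & ~known].dropna().unique())
        raise ValueError(f"unknown closed-format categories: {bad}")
    closed_weekly = closed.map(CLOSED_RECODE)

    daily = pd.Series(np.nan, index=obs.index, dtype=float)
    m = fmt == "weekday_weekend"
    daily[m] = (5.0 * wd[m] + 2.0 * we[m]) / 7.0
    m = fmt == "weekly_numeric"
    daily[m] = weekly[m] / 7.0
    daily[is_closed] = closed_weekly[is_closed] / 7.0
    return daily


def build_phenotype_table(
    observations: pd.DataFrame, *, impute_zero_cola: bool = False
) -> pd.DataFrame:
    """Derive the wide per-subject, per-time-point phenotype table.

    Composes format conversion, outlier masking (applied to the derived daily
    values) and the caffeine-weighted total. Caffeinated and decaffeinated
    streams are kept separate; decaf values never enter ``total_caffeine_mg``.

    Parameters
    ----------
    observations
        Long-format table with :data:`OBSERVATION_COLUMNS`.
    impute_zero_cola
        Sensitivity option: treat missing caffeinated cola as zero when
        forming the total (default: complete-case, total missing if any
        caffeinated component is).
    """
    obs = observations.copy()
    if obs.empty:
        return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    _validate_observations(obs)

    daily = _daily_values(obs)
    ceiling = obs["beverage"].map(OUTLIER_MAX_PER_DAY)
    daily = daily.where(~(daily > ceiling))  # strict ">" masking; NaN stays NaN

    caff = obs["caffeinated"].astype(bool)
    obs = obs.assign(
        _daily=daily,
        _col=np.where(caff, "", "decaf_") + obs["beverage"].astype(str) + "_per_day",
    )
    wide = obs.pivot_table(
        index=["subject_id", "time_point"],
        columns="_col",
        values="_daily",
        aggfunc="first",
        dropna=False,
    ).reset_index()
    wide.columns.name = None
    for col in PHENOTYPE_COLUMNS:
        if col not in wide.columns:
            wide[col] = np.nan

    cola = wide["cola_per_day"]
    if impute_zero_cola:
        cola = cola.fillna(0.0)
    wide["total_caffeine_mg"] = (
        CAFFEINE_MG_PER_DRINK["coffee"] * wide["coffee_per_day"]
        + CAFFEINE_MG_PER_DRINK["tea"] * wide["tea_per_day"]
        + CAFFEINE_MG_PER_DRINK["cola"] * cola
    )

    wide["time_point"] = pd.Categorical(wide["time_point"], categories=TIME_POINTS, ordered=True)
    wide = wide.sort_values(["subject_id", "time_point"], kind="stable").reset_index(drop=True)
    return wide[PHENOTYPE_COLUMNS]


def read_observations_tsv(path) -> pd.DataFrame:
    """Read a long-format observation TSV (empty string = null)."""
    obs = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "closed_category": str},
        keep_default_na=True,
        na_values=[""],
    )
    if "caffeinated" in obs.columns and obs["caffeinated"].dtype == object:
        obs["caffeinated"] = obs["caffeinated"].map(
            {"True": True, "False": False, "true": True, "false": False, True: True, False: False}
        )
    return obs


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="")
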