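"""Genetic-instrument validation: confounder balance and negative controls.

A genotype usable as a Mendelian-randomization instrument must predict the
exposure but not its confounders. This module checks (a) that genotypes and
the allelic score are unassociated with measured confounders (year of birth,
housing tenure, crowding, education, alcohol, tobacco), (b) that — by
contrast — the caffeine phenotype itself is strongly confounded, and (c)
that the genotypes show no association with decaffeinated drink consumption,
a negative-control exposure sharing the behavioural but not the
pharmacological determinants of the caffeinated phenotypes.

Categorical confounders are ordinal-coded and treated as numeric (linearity
imposed); each confounder is tested marginally, one regression at a time.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    DEFAULT_PREDICTORS,
    _predictor_series,
    association_sweep,
    ols_additive,
    results_to_frame,
)

#: Confounder table columns, in Table layout order.
CONFOUNDER_COLUMNS = [
    "year_of_birth",
    "housing_tenure",
    "crowding_index",
    "education_level",
    "alcohol",
    "tobacco",
]

#: decaf phenotype label -> phenotype-table column.
DECAF_COLUMNS: dict[str, str] = {
    "decaf_coffee": "decaf_coffee_per_day",
    "decaf_tea": "decaf_tea_per_day",
    "decaf_cola": "decaf_cola_per_day",
}


def _check_confounders(confounders: pd.DataFrame) -> None:
    missing = [c for c in CONFOUNDER_COLUMNS if c not in confounders.columns]
    if missing:
        raise ValueError(f"confounder table missing columns: {missing}")


def confounder_balance(
    genotypes: pd.DataFrame,
    confounders: pd.DataFrame,
    *,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    confounder_columns: Sequence[str] = tuple(CONFOUNDER_COLUMNS),
) -> pd.DataFrame:
    """Regress each confounder on each genetic predictor (one at a time).

    ``genotypes`` is subject-indexed hard calls per rsid; ``confounders`` is
    subject-indexed (or has a subject_id column). A well-behaved instrument
    shows null associations throughout. Constant confounders are flagged in
    ``attrs["skipped"]`` rather than raised; an empty subject overlap is an
    error.
    """
    conf = confounders.set_index("subject_id") if "subject_id" in confounders.columns else confounders
    _check_confounders(conf)
    common = genotypes.index.intersection(conf.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between genotype and confounder tables")
    geno = genotypes.loc[common]
    conf = conf.loc[common]

    rows: list[AssociationResult] = []
    skipped: list[tuple[str, str, str]] = []
    for name in confounder_columns:
        y = conf[name].astype(float).to_numpy()
        if np.nanvar(y) == 0.0:
            skipped.append((name, "*", "constant confounder"))
            continue
        for pred in predictors:
            x = _predictor_series(geno, pred).to_numpy()
            try:
                rows.append(
                    ols_additive(y, x, phenotype_label=name, time_point="", predictor_label=pred)
                )
            except ValueError as exc:
                skipped.append((name, pred, str(exc)))
    out = results_to_frame(rows)
    out.attrs["skipped"] = skipped
    return out


def phenotype_confounding(
    phenotypes: pd.DataFrame,
    confounders: pd.DataFrame,
    *,
    phenotype_column: str = "total_caffeine_mg",
    time_points: Sequence[str] = ("18wk", "47mo", "145mo"),
    confounder_columns: Sequence[str] = tuple(CONFOUNDER_COLUMNS),
) -> pd.DataFrame:
    """Regress the caffeine phenotype on each confounder, per time point.

    The observational counterpart of :func:`confounder_balance`: strong
    associations here, with null genotype-confounder associations, are what
    motivate the genotypes as instruments.
    """
    conf = confounders.set_index("subject_id") if "subject_id" in confounders.columns else confounders
    _check_confounders(conf)
    rows: list[AssociationResult] = []
    skipped: list[tuple[str, str, str]] = []
    for tp in time_points:
        chunk = phenotypes[phenotypes["time_point"].astype(str) == str(tp)]
        merged = chunk.merge(conf, left_on="subject_id", right_index=True, how="inner")
        if merged.empty:
            raise ValueError(f"no subjects shared with confounder table at {tp}")
        y = merged[phenotype_column].astype(float).to_numpy()
        for name in confounder_columns:
            x = merged[name].astype(float).to_numpy()
            try:
                rows.append(
                    ols_additive(y, x, phenotype_label=name, time_point=str(tp), predictor_label=phenotype_column)
                )
            except ValueError as exc:
                skipped.append((str(tp), name, str(exc)))
    out = results_to_frame(rows)
    out.attrs["skipped"] = skipped
    return out


def negative_control(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    *,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    decaf_columns: Mapping[str, str] = DECAF_COLUMNS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association sweep on the decaffeinated phenotypes.

    Runs exactly the same machinery as the caffeinated sweep on the decaf
    columns and annotates each cell with ``consistent_with_null`` (p >
    ``alpha``, two-sided, uncorrected — a report annotation, not an
    inferential claim). If the instrument acts through caffeine, every cell
    should be consistent with null.
    """
    missing = [c for c in decaf_columns.values() if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"decaf phenotype columns missing: {missing}")
    out = association_sweep(
        phenotypes, genotypes, predictors=predictors, phenotype_columns=dict(decaf_columns)
    )
    out["consistent_with_null"] = out["p_value"] > alpha
    return out
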