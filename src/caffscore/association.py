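"""Additive genetic association models across time points.

Each phenotype (total caffeine mg/day; coffee, tea, cola drinks/day) is
regressed on a per-subject T-allele count — a single SNP, the unweighted
2-SNP score, or the effect-size-weighted score — by ordinary least squares,
separately at each questionnaire time point with per-cell complete cases.
Departures from additivity are tested with a heterozygote (dominance) term
within locus and a genotype product (epistasis) term between loci.

The regression core is closed-form (simple OLS and small fixed designs) so
that Monte-Carlo calibration studies with thousands of replicate fits stay
cheap; it is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import SCORE_WEIGHTS, TIME_POINTS, VARIANT_IDS
from .genetics import combined_score

#: phenotype label -> phenotype-table column, in report order.
PHENOTYPE_COLUMNS: dict[str, str] = {
    "total": "total_caffeine_mg",
    "coffee": "coffee_per_day",
    "tea": "tea_per_day",
    "cola": "cola_per_day",
}

DEFAULT_PREDICTORS = (VARIANT_IDS[0], VARIANT_IDS[1], "combined")

RESULT_COLUMNS = [
    "phenotype",
    "time_point",
    "predictor",
    "n",
    "beta",
    "se",
    "p_value",
    "r_squared",
    "mean",
    "sd",
    "min",
    "max",
]


@dataclass
class AssociationResult:
    """One fitted cell: beta/SE/p/N/R^2 for a predictor x phenotype x time point."""

    phenotype_label: str
    time_point: str
    predictor_label: str
    n: int
    beta: float
    se: float
    p_value: float
    r_squared: float
    mean: float = np.nan
    sd: float = np.nan
    min: float = np.nan
    max: float = np.nan


@dataclass
class NonAdditivityResult:
    """Estimate, SE and p for a dominance or epistasis term."""

    test_kind: str  # "within_locus" | "between_locus"
    term_estimate: float
    term_se: float
    p_value: float
    n: int


def _complete_cases(*arrays) -> tuple[np.ndarray, ...]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    if len({c.shape for c in cols}) != 1:
        raise ValueError(f"misaligned inputs: shapes {[c.shape for c in cols]}")
    keep = ~np.any([np.isnan(c) for c in cols], axis=0)
    return tuple(c[keep] for c in cols)


def ols_additive(
    phenotype,
    predictor,
    *,
    phenotype_label: str = "",
    time_point: str = "",
    predictor_label: str = "",
) -> AssociationResult:
    """Simple linear regression of phenotype on an additive allele count.

    Complete-case: pairs with either value missing are dropped. The slope SE
    comes from the residual variance and the two-sided p-value from the t
    distribution with n - 2 degrees of freedom; R^2 is the squared sample
    correlation.
    """
    y, x = _complete_cases(phenotype, predictor)
    n = y.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    sxx = float(np.var(x))
    if sxx == 0.0:
        raise ValueError("zero predictor variance (monomorphic score)")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    beta = sxy / sxx
    resid = (y - y.mean()) - beta * (x - x.mean())
    sse = float(resid @ resid)
    syy = float(np.var(y)) * n
    if sse <= 0.0 or syy == 0.0:
        # perfect fit or constant response: p degenerates
        se = 0.0
        p = 1.0 if syy == 0.0 else 0.0
        r2 = 0.0 if syy == 0.0 else 1.0
    else:
        sigma2 = sse / (n - 2)
        se = float(np.sqrt(sigma2 / (n * sxx)))
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        r2 = float(1.0 - sse / syy)
    return AssociationResult(
        phenotype_label=phenotype_label,
        time_point=time_point,
        predictor_label=predictor_label,
        n=n,
        beta=float(beta),
        se=se,
        p_value=max(p, np.finfo(float).tiny),
        r_squared=r2,
        mean=float(y.mean()),
        sd=float(y.std(ddof=1)) if n > 1 else np.nan,
        min=float(y.min()),
        max=float(y.max()),
    )


def variance_explained_analytic(beta: float, score_variance: float, phenotype_variance: float) -> float:
    """Proportion of phenotypic variance explained: beta^2 * var(score) / var(y).

    For a single SNP in Hardy-Weinberg proportions at effect-allele
    frequency q, ``score_variance = 2 q (1 - q)``.
    """
    if score_variance <= 0 or phenotype_variance <= 0:
        raise ValueError("variances must be strictly positive")
    return beta**2 * score_variance / phenotype_variance


def hwe_score_variance(q: float) -> float:
    """Variance of a single-SNP allele count under Hardy-Weinberg: 2q(1-q)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {q}")
    return 2.0 * q * (1.0 - q)


def _ols_multi(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit returning (coefficients, SEs, residual df, residual variance)."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise ValueError("degenerate design: collinear columns")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - k)
    ses = np.sqrt(np.diag(xtx_inv) * sigma2)
    return coef, ses, n - k, sigma2


def _term_p(estimate: float, se: float, dof: int, *, perfect: bool, y_scale: float) -> float:
    """Two-sided t p-value, handling numerically-perfect (noiseless) fits."""
    if perfect or se == 0.0:
        # perfect fit: a non-zero term is unambiguous, a zero one is null
        p = 0.0 if abs(estimate) > 1e-9 * max(y_scale, 1.0) else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(estimate / se), df=dof))
    return max(p, np.finfo(float).tiny)


def dominance_test(phenotype, genotype_calls) -> NonAdditivityResult:
    """Within-locus non-additivity: significance of a heterozygote term.

    Fits phenotype ~ allele count + 1{heterozygote}; under pure additivity
    the heterozygote coefficient is zero. All three genotype classes must be
    present.
    """
    y, g = _complete_cases(phenotype, genotype_calls)
    present = set(np.unique(g))
    missing_classes = sorted({0.0, 1.0, 2.0} - present)
    if missing_classes:
        raise ValueError(f"genotype classes absent from sample: {missing_classes}")
    X = np.column_stack([np.ones_like(g), g, (g == 1.0).astype(float)])
    coef, ses, dof, sigma2 = _ols_multi(X, y)
    perfect = sigma2 <= 1e-18 * max(float(np.var(y)), 1e-300)
    p = _term_p(coef[2], ses[2], dof, perfect=perfect, y_scale=float(np.std(y)))
    return NonAdditivityResult("within_locus", float(coef[2]), float(ses[2]), p, y.size)


def interaction_test(phenotype, calls_snp1, calls_snp2) -> NonAdditivityResult:
    """Between-locus non-additivity: significance of the genotype product term.

    Fits phenotype ~ g1 + g2 + g1*g2; under independent additive effects the
    product coefficient is zero.
    """
    y, g1, g2 = _complete_cases(phenotype, calls_snp1, calls_snp2)
    for name, g in (("snp1", g1), ("snp2", g2)):
        if np.var(g) == 0.0:
            raise ValueError(f"{name} is monomorphic in the analysed sample")
    X = np.column_stack([np.ones_like(g1), g1, g2, g1 * g2])
    coef, ses, dof, sigma2 = _ols_multi(X, y)
    perfect = sigma2 <= 1e-18 * max(float(np.var(y)), 1e-300)
    p = _term_p(coef[3], ses[3], dof, perfect=perfect, y_scale=float(np.std(y)))
    return NonAdditivityResult("between_locus", float(coef[3]), float(ses[3]), p, y.size)


def _predictor_series(genotypes: pd.DataFrame, predictor: str) -> pd.Series:
    g1, g2 = genotypes[VARIANT_IDS[0]], genotypes[VARIANT_IDS[1]]
    if predictor in genotypes.columns:
        return genotypes[predictor].astype(float)
    if predictor == "combined":
        return combined_score(g1, g2)
    if predictor == "weighted":
        return combined_score(g1, g2, weights=SCORE_WEIGHTS)
    raise ValueError(f"unknown predictor {predictor!r}")


def association_sweep(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    *,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    phenotype_columns: Mapping[str, str] = PHENOTYPE_COLUMNS,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Fit every phenotype x time point x predictor cell.

    ``phenotypes`` is the wide refinement output (one row per subject x time
    point); ``genotypes`` a subject-indexed table of hard calls per rsid.
    Cells that cannot be fitted (absent column, < 3 complete pairs, or a
    monomorphic predictor) are omitted and listed in ``result.attrs["skipped"]``.
    With ``positive_only`` each cell is restricted to subjects reporting
    strictly positive consumption of the analysed phenotype.

    Returns a DataFrame in deterministic (time, phenotype, predictor) order.
    """
    merged = phenotypes.merge(
        genotypes, left_on="subject_id", right_index=True, how="inner"
    )
    if merged.empty:
        raise ValueError("empty join between phenotype and genotype tables")

    rows: list[AssociationResult] = []
    skipped: list[tuple[str, str, str, str]] = []
    time_order = [t for t in TIME_POINTS if t in set(merged["time_point"].astype(str))]
    for tp in time_order:
        chunk = merged[merged["time_point"].astype(str) == tp]
        for label, col in phenotype_columns.items():
            if col not in chunk.columns or chunk[col].notna().sum() == 0:
                skipped.append((tp, label, "*", "no phenotype data"))
                continue
            y_all = chunk[col].astype(float)
            if positive_only:
                y_all = y_all.where(y_all > 0)
            for pred in predictors:
                try:
                    x = _predictor_series(chunk[list(genotypes.columns)], pred)
                    rows.append(
                        ols_additive(
                            y_all.to_numpy(),
                            x.to_numpy(),
                            phenotype_label=label,
                            time_point=tp,
                            predictor_label=pred,
                        )
                    )
                except ValueError as exc:
                    skipped.append((tp, label, pred, str(exc)))
    out = results_to_frame(rows)
    out.attrs["skipped"] = skipped
    return out


def zero_consumer_sensitivity(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    *,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    phenotype_columns: Mapping[str, str] = PHENOTYPE_COLUMNS,
) -> pd.DataFrame:
    """Sensitivity sweep excluding subjects who report zero consumption.

    Cells whose stratum is empty after exclusion are reported in
    ``attrs["skipped"]``, not raised.
    """
    return association_sweep(
        phenotypes,
        genotypes,
        predictors=predictors,
        phenotype_columns=phenotype_columns,
        positive_only=True,
    )


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "phenotype": r.phenotype_label,
                "time_point": r.time_point,
                "predictor": r.predictor_label,
                "n": r.n,
                "beta": r.beta,
                "se": r.se,
                "p_value": r.p_value,
                "r_squared": r.r_squared,
                "mean": r.mean,
                "sd": r.sd,
                "min": r.min,
                "max": r.max,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    return frame
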