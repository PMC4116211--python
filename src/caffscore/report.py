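"""Rendering of association results into the published table layouts.

Layouts ``table1``-``table4`` are per-time-point association tables (one per
phenotype: total caffeine, coffee, tea, cola) with Time, N, Mean, SD, Min,
Max then Beta/SE/P-Value blocks per predictor. ``table5`` is the
genotype-vs-confounder balance table and ``table6`` the phenotype-vs-
confounder table across three time points. Decaf negative-control sweeps
reuse the table1-4 shape via :func:`render_association_table`.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .constants import TIME_POINTS, VARIANT_IDS
from .validation import CONFOUNDER_COLUMNS

#: layout name -> phenotype label of the association sweep.
TABLE_PHENOTYPES = {"table1": "total", "table2": "coffee", "table3": "tea", "table4": "cola"}

_PREDICTOR_HEADER = {
    VARIANT_IDS[0]: "CYP1A1 rs2472297",
    VARIANT_IDS[1]: "AHR rs6968865",
    "combined": "Combined Score",
    "weighted": "Weighted Score",
    "total_caffeine_mg": "Total Caffeine",
}

_CONFOUNDER_LABEL = {
    "year_of_birth": "Year of Birth",
    "housing_tenure": "Housing Tenure",
    "crowding_index": "Crowding Index",
    "education_level": "Educational Level",
    "alcohol": "Alcohol Consumption",
    "tobacco": "Tobacco Consumption",
}


def _fmt(value, digits: int) -> str:
    if value is None or pd.isna(value):
        return "NA"
    return f"{value:.{digits}f}"


def _fmt_p(p) -> str:
    if p is None or pd.isna(p):
        return "NA"
    return f"{p:.2e}"


def _cell(results: pd.DataFrame, digits: int, warn_context: str, **filters) -> list[str]:
    mask = pd.Series(True, index=results.index)
    for col, val in filters.items():
        mask &= results[col].astype(str) == str(val)
    sub = results[mask]
    if sub.empty:
        warnings.warn(f"missing cell {filters} in {warn_context}; rendered as NA")
        return ["NA", "NA", "NA"]
    r = sub.iloc[0]
    return [_fmt(r["beta"], digits), _fmt(r["se"], digits), _fmt_p(r["p_value"])]


def render_association_table(
    results: pd.DataFrame,
    phenotype: str,
    *,
    predictors: Sequence[str] = (VARIANT_IDS[0], VARIANT_IDS[1], "combined"),
    beta_digits: int | None = None,
) -> str:
    """Render one phenotype's sweep as a TSV table in the published layout.

    mg-scale phenotypes get 1-decimal betas/SEs, drink-scale ones 3 decimals;
    p-values use 2-significant-digit scientific notation (3.74e-14).
    """
    if beta_digits is None:
        beta_digits = 1 if phenotype == "total" else 3
    sub = results[results["phenotype"] == phenotype]
    header1 = ["Time", "N", "Mean", "SD", "Min", "Max"]
    for pred in predictors:
        header1 += [_PREDICTOR_HEADER.get(pred, pred), "", ""]
    header2 = ["", "", "", "", "", ""] + ["Beta", "SE", "P-Value"] * len(predictors)
    lines = ["\t".join(header1), "\t".join(header2)]
    if sub.empty:
        warnings.warn(f"no results for phenotype {phenotype!r}: header-only table")
        return "\n".join(lines) + "\n"
    summary_digits = 1 if phenotype == "total" else 2
    for tp in [t for t in TIME_POINTS if t in set(sub["time_point"].astype(str))]:
        at_tp = sub[sub["time_point"].astype(str) == tp]
        first = at_tp.iloc[0]
        row = [
            tp,
            str(int(first["n"])),
            _fmt(first["mean"], summary_digits),
            _fmt(first["sd"], summary_digits),
            _fmt(first["min"], 0),
            _fmt(first["max"], 0),
        ]
        for pred in predictors:
            row += _cell(at_tp, beta_digits, f"phenotype {phenotype}", predictor=pred)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def render_confounder_balance_table(
    results: pd.DataFrame,
    *,
    predictors: Sequence[str] = (VARIANT_IDS[0], VARIANT_IDS[1], "combined"),
) -> str:
    """Render the genotype-vs-confounder balance results (table5 layout)."""
    header1 = ["", "N"]
    for pred in predictors:
        header1 += [_PREDICTOR_HEADER.get(pred, pred), "", ""]
    header2 = ["", ""] + ["Beta", "SE", "P-Value"] * len(predictors)
    lines = ["\t".join(header1), "\t".join(header2)]
    for name in CONFOUNDER_COLUMNS:
        sub = results[results["phenotype"] == name]
        n = str(int(sub["n"].max())) if not sub.empty else "NA"
        row = [_CONFOUNDER_LABEL[name], n]
        for pred in predictors:
            row += _cell(results, 3, "confounder balance", phenotype=name, predictor=pred)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def render_phenotype_confounding_table(
    results: pd.DataFrame, *, time_points: Sequence[str] = ("18wk", "47mo", "145mo")
) -> str:
    """Render the phenotype-vs-confounder results per time point (table6 layout)."""
    header1 = ["", "N"] + [tp for tp in time_points for _ in range(3)]
    header2 = ["", ""] + ["Beta", "SE", "P-Value"] * len(time_points)
    lines = ["\t".join(header1), "\t".join(header2)]
    for name in CONFOUNDER_COLUMNS:
        sub = results[results["phenotype"] == name]
        if sub.empty:
            n = "NA"
        else:
            lo, hi = int(sub["n"].min()), int(sub["n"].max())
            n = f"{hi}-{lo}" if hi != lo else str(hi)
        row = [_CONFOUNDER_LABEL[name], n]
        for tp in time_points:
            row += _cell(results, 3, "phenotype confounding", phenotype=name, time_point=tp)
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def render_table(results: pd.DataFrame, layout: str) -> str:
    """Dispatch on layout name (``table1`` .. ``table6``)."""
    if layout in TABLE_PHENOTYPES:
        return render_association_table(results, TABLE_PHENOTYPES[layout])
    if layout == "table5":
        return render_confounder_balance_table(results)
    if layout == "table6":
        return render_phenotype_confounding_table(results)
    raise ValueError(f"unknown layout {layout!r}; expected table1..table6")
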