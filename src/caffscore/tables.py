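"""Packaged per-time-point summary constants used to parameterize simulations.

The package ships a plain-text table (``data/table_constants.tsv``) holding,
for every phenotype x time point: the analysed N, phenotype mean and SD, and
the per-T-allele regression estimates (beta/SE/p) for rs2472297, rs6968865
and the unweighted combined score. :func:`scenario_from_table` turns one row
into the generating parameters of a simulation scenario.

Units: total caffeine in mg/day; coffee and tea in drinks/day; cola in
drinks/week.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd


@dataclass(frozen=True)
class Scenario:
    """Generating parameters for one phenotype x time point."""

    phenotype: str
    time_point: str
    n: int
    mean: float
    sd: float
    beta_rs2472297: float
    se_rs2472297: float
    beta_rs6968865: float
    se_rs6968865: float
    beta_combined: float
    se_combined: float


@lru_cache(maxsize=1)
def load_table_constants() -> pd.DataFrame:
    """Load the packaged constants table (cached)."""
    ref = importlib.resources.files("caffscore.data").joinpath("table_constants.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return df


def scenario_from_table(time_point: str, phenotype: str) -> Scenario:
    """Return the generating parameters for one stored row.

    ``phenotype`` is one of total/coffee/tea/cola; ``time_point`` one of the
    eight questionnaire waves (e.g. ``"145mo"``). Unknown rows are an error.
    """
    df = load_table_constants()
    row = df[(df["phenotype"] == phenotype) & (df["time_point"] == time_point)]
    if row.empty:
        known_p = sorted(df["phenotype"].unique())
        known_t = list(df["time_point"].unique()[:8])
        raise ValueError(
            f"no scenario for phenotype={phenotype!r}, time_point={time_point!r}; "
            f"phenotypes: {known_p}, time points: {known_t}"
        )
    r = row.iloc[0]
    return Scenario(
        phenotype=phenotype,
        time_point=time_point,
        n=int(r["n"]),
        mean=float(r["mean"]),
        sd=float(r["sd"]),
        beta_rs2472297=float(r["beta_rs2472297"]),
        se_rs2472297=float(r["se_rs2472297"]),
        beta_rs6968865=float(r["beta_rs6968865"]),
        se_rs6968865=float(r["se_rs6968865"]),
        beta_combined=float(r["beta_combined"]),
        se_combined=float(r["se_combined"]),
    )
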