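"""Shared constants: questionnaire scoring, variant definitions and QC thresholds.

The numeric constants here define the phenotype-harmonization and scoring
conventions used throughout the package: caffeine content per drink (mg),
outlier ceilings on daily consumption, the recode table for closed-format
weekly-frequency responses, and the two caffeine-associated SNPs (rs2472297
near CYP1A1/CYP1A2, rs6968865 near AHR) whose T alleles are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Approximate caffeine content per drink, mg.
CAFFEINE_MG_PER_DRINK: dict[str, float] = {"coffee": 75.0, "tea": 40.0, "cola": 34.5}

#: Daily-consumption ceilings; values strictly above these are set to missing.
OUTLIER_MAX_PER_DAY: dict[str, float] = {"coffee": 10.0, "tea": 15.0, "cola": 21.0}

#: Closed-format frequency categories -> drinks per week, in increasing order.
CLOSED_RECODE: dict[str, float] = {
    "never or rarely": 0.0,
    "once in 2 weeks": 0.5,
    "1 to 3 times a week": 2.0,
    "4 to 7 times a week": 5.5,
    "once a day or more": 7.0,
}

#: Questionnaire time points in chronological order (gestation weeks, then
#: months after delivery).
TIME_POINTS: tuple[str, ...] = ("8wk", "18wk", "32wk", "2mo", "47mo", "85mo", "97mo", "145mo")

BEVERAGES: tuple[str, ...] = ("coffee", "tea", "cola")

OBSERVATION_FORMATS: tuple[str, ...] = ("weekday_weekend", "weekly_numeric", "weekly_closed")

#: The counted (effect) allele at both loci.
EFFECT_ALLELE = "T"

#: rsid -> population T-allele frequency.
EFFECT_ALLELE_FREQS: dict[str, float] = {"rs2472297": 0.27, "rs6968865": 0.61}

VARIANT_IDS: tuple[str, str] = ("rs2472297", "rs6968865")

#: Published per-allele weights for the weighted allelic score.
SCORE_WEIGHTS: dict[str, float] = {"rs2472297": 0.31, "rs6968865": 0.26}


@dataclass(frozen=True)
class QCThresholds:
    """Variant- and individual-level QC cutoffs.

    A variant is kept iff MAF >= maf_min, call rate >= call_rate_min and the
    exact Hardy-Weinberg p-value is strictly greater than hwe_p_min.
    Individuals with a missing-genotype fraction above
    individual_missingness_max are removed before variant metrics are
    computed.
    """

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 5e-6
    individual_missingness_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "individual_missingness_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
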