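"""Synthetic cohort generator with the statistical structure the analysis assumes.

Real questionnaire + genotype data for this design are managed-access, so
every stage of the pipeline is exercised on simulated cohorts whose
generating parameters come from the packaged per-time-point constants
(:mod:`caffscore.tables`): Hardy-Weinberg genotypes at T-allele frequencies
0.27 (rs2472297) and 0.61 (rs6968865), beverage consumption with the
published marginal means/SDs and additive per-allele effects on the
caffeinated streams only, zero genotype effect on decaffeinated streams and
cola, and confounders built from the non-genetic phenotype residual so that
genotype and confounders are independent by construction.

The generative model per beverage, subject i and time point t is

    y_it = mu_adj + beta1 * g1_i + beta2 * g2_i + eps_it,
    eps_it ~ Normal(0, sigma_resid),

with mu_adj and sigma_resid chosen so the marginal mean and SD equal the
configured values. The latent noise is untruncated by default so OLS
recovery targets are unbiased; rendering into questionnaire form clamps
negative values at zero (counts cannot be negative) and the truth table
records both the latent and the rendered value.

All randomness flows from one master seed; each output table draws from its
own labelled substream, so adding a table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    CAFFEINE_MG_PER_DRINK,
    CLOSED_RECODE,
    EFFECT_ALLELE_FREQS,
    TIME_POINTS,
    VARIANT_IDS,
)
from .phenotype import OBSERVATION_COLUMNS
from .tables import scenario_from_table
from .validation import CONFOUNDER_COLUMNS

# fixed substream labels (master seed, label) -> independent generator
_STREAM = {"genotypes": 1, "consumption": 2, "decaf": 3, "confounders": 4, "missingness": 5, "outliers": 6}

#: time points at which cola is asked in closed (category) format.
CLOSED_COLA_TIME_POINTS: tuple[str, ...] = ("47mo", "85mo", "97mo", "145mo")


@dataclass(frozen=True)
class VariantSpec:
    rsid: str
    effect_allele_freq: float
    imputation_quality: float | None = None


DEFAULT_VARIANTS: tuple[VariantSpec, VariantSpec] = (
    VariantSpec("rs2472297", EFFECT_ALLELE_FREQS["rs2472297"], None),
    VariantSpec("rs6968865", EFFECT_ALLELE_FREQS["rs6968865"], 0.96),
)

#: confounder -> effect of the standardized non-genetic 18wk caffeine
#: residual on the confounder's latent scale (sign pattern of the
#: observational confounding: heavier caffeine use goes with renting,
#: crowding, less education, more alcohol and tobacco).
DEFAULT_CONFOUNDER_GAMMAS: dict[str, float] = {
    "year_of_birth": -0.05,
    "housing_tenure": 0.35,
    "crowding_index": 0.30,
    "education_level": -0.35,
    "alcohol": 0.30,
    "tobacco": 0.45,
}

#: confounder -> affine scale applied to the latent (units of the confounder
#: per latent SD); ordinals are thresholded instead.
_CONFOUNDER_SCALE: dict[str, float] = {
    "year_of_birth": 4.0,
    "crowding_index": 0.35,
    "alcohol": 3.0,
    "tobacco": 3.0,
}
_CONFOUNDER_OFFSET: dict[str, float] = {
    "year_of_birth": 1962.0,
    "crowding_index": 0.7,
    "alcohol": 3.0,
    "tobacco": 2.0,
}

#: decaffeinated stream marginals (drinks/day for coffee & tea, drinks/week
#: for cola): modest consumption, constant across time points. No reference
#: values exist; chosen once as plausible for a 1990s UK pregnancy cohort.
DEFAULT_DECAF_MEANS: dict[str, float] = {"coffee": 0.35, "tea": 0.40, "cola": 0.80}
DEFAULT_DECAF_SDS: dict[str, float] = {"coffee": 0.90, "tea": 1.00, "cola": 1.80}


@dataclass
class SimulationConfig:
    """All generative parameters of a synthetic cohort."""

    n: int = 8000
    seed: int = 0
    variants: tuple[VariantSpec, VariantSpec] = DEFAULT_VARIANTS
    time_points: tuple[str, ...] = TIME_POINTS
    closed_format_time_points: tuple[str, ...] = CLOSED_COLA_TIME_POINTS
    missingness: float = 0.05
    outlier_rate: float = 0.0
    noise_model: str = "normal"  # "normal" | "censored"
    cola_genotype_effect: float = 0.0
    confounder_gammas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_GAMMAS)
    )
    decaf_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DECAF_MEANS))
    decaf_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DECAF_SDS))

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError(f"cohort size must be >= 10, got {self.n}")
        for v in self.variants:
            if not 0.0 < v.effect_allele_freq < 1.0:
                raise ValueError(f"{v.rsid}: allele frequency must be in (0,1)")
            if v.imputation_quality is not None and not 0.0 < v.imputation_quality <= 1.0:
                raise ValueError(f"{v.rsid}: imputation quality must be in (0,1]")
        if self.noise_model not in ("normal", "censored"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.missingness < 1.0 or not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("missingness and outlier_rate must be in [0,1)")


@dataclass
class SyntheticCohort:
    """Generated tables, all sharing the same subject ids."""

    genotypes: pd.DataFrame  # subject-indexed hard calls per rsid
    dosages: pd.DataFrame  # subject-indexed dosages per rsid
    observations: pd.DataFrame  # long questionnaire form, caffeinated + decaf
    confounders: pd.DataFrame  # subject-indexed confounder table
    truth: pd.DataFrame  # latent and rendered values per subject x time
    config: SimulationConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        from .genetics import write_dosage_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dosage_tsv(self.dosages, outdir / "dosages.tsv")
        write_dosage_tsv(self.genotypes, outdir / "genotypes.tsv")
        self.observations.to_csv(outdir / "observations.tsv", sep="\t", index=False, na_rep="")
        self.confounders.reset_index().to_csv(
            outdir / "confounders.tsv", sep="\t", index=False, na_rep=""
        )
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, na_rep="")


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one labelled output table."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM[label])))


def simulate_genotypes(
    n: int,
    effect_allele_freq: float,
    imputation_quality: float | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Hardy-Weinberg hard calls and (optionally noisy) dosages.

    Hard calls are Binomial(2, q) effect-allele counts. When an imputation
    quality r^2 < 1 is given, dosages are the calls plus Gaussian noise
    scaled so corr^2(dosage, call) ~= r^2, clipped to [0, 2]; otherwise the
    dosage equals the call.
    """
    q = effect_allele_freq
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency must be in (0,1), got {q}")
    if rng is None:
        rng = np.random.default_rng(seed)
    calls = rng.binomial(2, q, size=n).astype(float)
    if imputation_quality is None or imputation_quality >= 1.0:
        return calls, calls.copy()
    var_call = 2.0 * q * (1.0 - q)
    noise_sd = np.sqrt(var_call * (1.0 - imputation_quality) / imputation_quality)
    dosages = np.clip(calls + rng.normal(0.0, noise_sd, size=n), 0.0, 2.0)
    return calls, dosages


def simulate_trait(
    g1: np.ndarray,
    g2: np.ndarray,
    *,
    mean: float,
    sd: float,
    beta1: float,
    beta2: float,
    q1: float,
    q2: float,
    rng: np.random.Generator,
    noise_model: str = "normal",
) -> np.ndarray:
    """One phenotype draw per subject under the additive two-locus model.

    The intercept and residual SD are calibrated so the marginal mean and SD
    equal ``mean`` and ``sd`` (residual variance = sd^2 minus the additive
    genetic variance under HWE). Raises if the genetic variance alone
    exceeds sd^2.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    genetic_var = beta1**2 * 2 * q1 * (1 - q1) + beta2**2 * 2 * q2 * (1 - q2)
    resid_var = sd**2 - genetic_var
    if resid_var < 0:
        raise ValueError(
            f"infeasible SD: genetic variance {genetic_var:.4g} exceeds total {sd**2:.4g}"
        )
    mu_adj = mean - 2.0 * (beta1 * q1 + beta2 * q2)
    eps = rng.normal(0.0, np.sqrt(resid_var), size=g1.size)
    y = mu_adj + beta1 * g1 + beta2 * g2 + eps
    if noise_model == "censored":
        y = np.maximum(y, 0.0)
    return y


def residual_sd(sd: float, beta1: float, beta2: float, q1: float, q2: float) -> float:
    """Residual SD implied by a marginal SD and the additive genetic variance."""
    genetic_var = beta1**2 * 2 * q1 * (1 - q1) + beta2**2 * 2 * q2 * (1 - q2)
    if sd**2 < genetic_var:
        raise ValueError("infeasible SD")
    return float(np.sqrt(sd**2 - genetic_var))


def _nearest_closed_category(weekly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map weekly values to the nearest closed-format recode value.

    Ties break toward the smaller category. Returns (labels, recode values).
    """
    labels = np.array(list(CLOSED_RECODE.keys()))
    values = np.array(list(CLOSED_RECODE.values()))
    dist = np.abs(weekly[:, None] - values[None, :])
    # argmin takes the first minimum -> smaller category wins ties
    idx = dist.argmin(axis=1)
    return labels[idx], values[idx]


def _beverage_params(config: SimulationConfig, beverage: str, tp: str) -> tuple[float, float, float, float]:
    """(mean, sd, beta1, beta2) for a caffeinated stream at one time point.

    Coffee and tea are in drinks/day with the published per-SNP effects;
    cola is in drinks/week with the configured (default zero) genotype
    effect on both SNPs.
    """
    sc = scenario_from_table(tp, beverage)
    if beverage == "cola":
        b = config.cola_genotype_effect
        return sc.mean, sc.sd, b, b
    return sc.mean, sc.sd, sc.beta_rs2472297, sc.beta_rs6968865


def simulate_consumption(
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
    decaf_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render latent consumption into questionnaire-form observation rows.

    Coffee and tea are rendered as equal weekday/weekend daily counts (an
    information-free split, so the 5/7-2/7 combiner is exercised without
    changing the value); cola as a weekly count, discretized to the closed
    categories at the configured later time points. Configured missingness
    and outlier injection are applied last. Returns (observations, truth);
    the truth table carries the latent daily values, the rendered
    (post-clamp, post-discretization) values, and the non-genetic residual
    of total caffeine used to build confounders.
    """
    rng = rng if rng is not None else substream(config.seed, "consumption")
    decaf_rng = decaf_rng if decaf_rng is not None else substream(config.seed, "decaf")
    miss_rng = substream(config.seed, "missingness")
    out_rng = substream(config.seed, "outliers")

    subjects = genotypes.index.to_numpy()
    g1 = genotypes[VARIANT_IDS[0]].to_numpy(dtype=float)
    g2 = genotypes[VARIANT_IDS[1]].to_numpy(dtype=float)
    q1, q2 = (v.effect_allele_freq for v in config.variants)
    n = subjects.size

    obs_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []

    for tp in config.time_points:
        truth: dict[str, np.ndarray] = {"subject_id": subjects, "time_point": np.repeat(tp, n)}
        resid_total = np.zeros(n)
        for caffeinated in (True, False):
            stream_rng = rng if caffeinated else decaf_rng
            prefix = "" if caffeinated else "decaf_"
            for beverage in ("coffee", "tea", "cola"):
                if caffeinated:
                    mean, sd, b1, b2 = _beverage_params(config, beverage, tp)
                else:
                    mean, sd, b1, b2 = config.decaf_means[beverage], config.decaf_sds[beverage], 0.0, 0.0
                mu_adj = mean - 2.0 * (b1 * q1 + b2 * q2)
                eps = stream_rng.normal(0.0, residual_sd(sd, b1, b2, q1, q2), size=n)
                latent = mu_adj + b1 * g1 + b2 * g2 + eps
                if config.noise_model == "censored":
                    latent = np.maximum(latent, 0.0)
                rendered = np.maximum(latent, 0.0)  # questionnaire counts are >= 0

                fmt = np.repeat("weekday_weekend", n).astype(object)
                wd = np.full(n, np.nan)
                we = np.full(n, np.nan)
                weekly = np.full(n, np.nan)
                closed = np.full(n, None, dtype=object)
                if beverage == "cola":
                    if tp in config.closed_format_time_points:
                        fmt[:] = "weekly_closed"
                        labels, values = _nearest_closed_category(rendered)
                        closed[:] = labels
                        rendered = values.astype(float)
                    else:
                        fmt[:] = "weekly_numeric"
                        weekly = rendered.copy()
                    rendered_daily = rendered / 7.0
                    latent_daily = latent / 7.0
                    resid_daily = eps / 7.0
                else:
                    wd = rendered.copy()
                    we = rendered.copy()
                    rendered_daily = rendered.copy()
                    latent_daily = latent
                    resid_daily = eps

                if config.outlier_rate > 0 and fmt[0] != "weekly_closed":
                    from .constants import OUTLIER_MAX_PER_DAY

                    inject = out_rng.random(n) < config.outlier_rate
                    if inject.any():
                        hi = OUTLIER_MAX_PER_DAY[beverage] + 1.0 + out_rng.exponential(2.0, size=int(inject.sum()))
                        if beverage == "cola":
                            weekly[inject] = hi * 7.0
                        else:
                            wd[inject] = hi
                            we[inject] = hi
                        rendered_daily = rendered_daily.copy()
                        rendered_daily[inject] = np.nan  # will be masked downstream

                # the truth's rendered value reflects the full deterministic
                # refinement chain, incl. masking of values above the ceiling
                from .constants import OUTLIER_MAX_PER_DAY as _CEIL

                rendered_daily = np.where(
                    rendered_daily > _CEIL[beverage], np.nan, rendered_daily
                )

                obs_frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": subjects,
                            "time_point": tp,
                            "beverage": beverage,
                            "caffeinated": caffeinated,
                            "format": fmt,
                            "weekday_count": wd,
                            "weekend_count": we,
                            "weekly_value": weekly if beverage == "cola" and fmt[0] == "weekly_numeric" else np.nan,
                            "closed_category": closed,
                        }
                    )
                )
                truth[f"{prefix}{beverage}_latent_per_day"] = latent_daily
                truth[f"{prefix}{beverage}_per_day_observed"] = rendered_daily
                if caffeinated:
                    resid_total = resid_total + CAFFEINE_MG_PER_DRINK[beverage] * resid_daily

        truth["total_caffeine_mg_latent"] = (
            CAFFEINE_MG_PER_DRINK["coffee"] * truth["coffee_latent_per_day"]
            + CAFFEINE_MG_PER_DRINK["tea"] * truth["tea_latent_per_day"]
            + CAFFEINE_MG_PER_DRINK["cola"] * truth["cola_latent_per_day"]
        )
        truth["total_caffeine_mg_observed"] = (
            CAFFEINE_MG_PER_DRINK["coffee"] * truth["coffee_per_day_observed"]
            + CAFFEINE_MG_PER_DRINK["tea"] * truth["tea_per_day_observed"]
            + CAFFEINE_MG_PER_DRINK["cola"] * truth["cola_per_day_observed"]
        )
        truth["resid_total_mg"] = resid_total
        truth_frames.append(pd.DataFrame(truth))

    observations = pd.concat(obs_frames, ignore_index=True)[OBSERVATION_COLUMNS]
    if config.missingness > 0:
        keep = miss_rng.random(len(observations)) >= config.missingness
        observations = observations[keep].reset_index(drop=True)
    truth_df = pd.concat(truth_frames, ignore_index=True)
    return observations, truth_df


def implied_phenotype_slope(gamma: float, scale: float, resid_sd: float) -> float:
    """Generating slope of phenotype on a continuous confounder.

    For confounder c = offset + scale*(gamma*z + e) with z the standardized
    phenotype residual and e ~ N(0,1) independent noise, the regression of
    the phenotype on c has slope gamma * resid_sd / (scale * (gamma^2 + 1)).
    """
    return gamma * resid_sd / (scale * (gamma**2 + 1.0))


def confounder_scale(name: str) -> float:
    """Affine scale used for a continuous confounder (units per latent SD)."""
    return _CONFOUNDER_SCALE[name]


def simulate_confounders(
    resid_z: np.ndarray,
    config: SimulationConfig,
    *,
    subjects: Sequence | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the confounder table from the standardized non-genetic residual.

    Each confounder's latent is gamma * z + e with fresh unit noise e, so
    confounders correlate with the phenotype through its residual only and
    are marginally independent of genotype by construction. Continuous
    confounders are affine in the latent (untruncated, so linear recovery is
    exact; crowding is floored at a small positive value); housing tenure
    (1-3) and education (1-5) are quantile-thresholded ordinals.
    """
    rng = rng if rng is not None else substream(config.seed, "confounders")
    z = np.asarray(resid_z, dtype=float)
    n = z.size
    gam = config.confounder_gammas
    out: dict[str, np.ndarray] = {}

    def latent(name: str) -> np.ndarray:
        return gam[name] * z + rng.normal(0.0, 1.0, size=n)

    def ordinal(c: np.ndarray, g: float, cum_probs: Sequence[float]) -> np.ndarray:
        sd = np.sqrt(g**2 + 1.0)
        cuts = stats.norm.ppf(cum_probs) * sd
        return (np.searchsorted(cuts, c) + 1).astype(float)

    out["year_of_birth"] = np.round(
        _CONFOUNDER_OFFSET["year_of_birth"] + _CONFOUNDER_SCALE["year_of_birth"] * latent("year_of_birth")
    )
    out["housing_tenure"] = ordinal(latent("housing_tenure"), gam["housing_tenure"], (0.70, 0.90))
    out["crowding_index"] = np.maximum(
        _CONFOUNDER_OFFSET["crowding_index"] + _CONFOUNDER_SCALE["crowding_index"] * latent("crowding_index"),
        0.05,
    )
    out["education_level"] = ordinal(
        latent("education_level"), gam["education_level"], (0.05, 0.25, 0.60, 0.85)
    )
    out["alcohol"] = _CONFOUNDER_OFFSET["alcohol"] + _CONFOUNDER_SCALE["alcohol"] * latent("alcohol")
    out["tobacco"] = _CONFOUNDER_OFFSET["tobacco"] + _CONFOUNDER_SCALE["tobacco"] * latent("tobacco")

    index = pd.Index(subjects, name="subject_id") if subjects is not None else pd.RangeIndex(n)
    return pd.DataFrame(out, index=index)[CONFOUNDER_COLUMNS]


def simulate_cohort(config: SimulationConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a full synthetic cohort (genotypes, questionnaire, confounders, truth)."""
    if config is None:
        config = SimulationConfig(**kwargs)
    geno_rng = substream(config.seed, "genotypes")
    subjects = pd.Index([f"S{i:06d}" for i in range(1, config.n + 1)], name="subject_id")
    calls: dict[str, np.ndarray] = {}
    doses: dict[str, np.ndarray] = {}
    for spec in config.variants:
        c, d = simulate_genotypes(
            config.n, spec.effect_allele_freq, spec.imputation_quality, rng=geno_rng
        )
        calls[spec.rsid], doses[spec.rsid] = c, d
    genotypes = pd.DataFrame(calls, index=subjects)
    dosages = pd.DataFrame(doses, index=subjects)

    observations, truth = simulate_consumption(genotypes, config)

    resid_18wk = truth.loc[truth["time_point"] == "18wk", "resid_total_mg"].to_numpy()
    z = (resid_18wk - resid_18wk.mean()) / resid_18wk.std()
    confounders = simulate_confounders(z, config, subjects=subjects)

    return SyntheticCohort(
        genotypes=genotypes,
        dosages=dosages,
        observations=observations,
        confounders=confounders,
        truth=truth,
        config=config,
    )
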