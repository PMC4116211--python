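"""Replicate simulation studies: parameter recovery at reference table rows.

Since the underlying cohort is managed-access, the pipeline's calibration is
demonstrated by parameter recovery: cohorts are simulated at the generating
parameters of a reference table row (sample size, phenotype mean/SD, T-allele
frequencies, per-allele effects), the association model is fitted per
cohort, and the replicate mean of the fitted coefficient is compared with
the generating value on the Monte-Carlo standard-error scale.

Two effect parameterizations are supported: ``equal_combined`` injects the
row's combined-score coefficient identically at both loci (so the
combined-score regression targets exactly that value), and ``per_snp``
injects each locus's own univariate coefficient (so single-SNP regressions
target the reference per-SNP values; the loci are independent, hence no
cross-contamination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import ols_additive
from .constants import EFFECT_ALLELE_FREQS, VARIANT_IDS
from .simulate import simulate_genotypes, simulate_trait
from .tables import Scenario, scenario_from_table


@dataclass
class RecoveryStudy:
    """Replicate-level fits from one simulation study."""

    scenario: Scenario
    predictor: str
    effects: str
    betas: np.ndarray
    ses: np.ndarray
    r_squareds: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.betas.size

    @property
    def mean_beta(self) -> float:
        return float(self.betas.mean())

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the replicate mean coefficient."""
        return float(self.betas.std(ddof=1) / np.sqrt(self.betas.size))

    @property
    def mean_se(self) -> float:
        return float(self.ses.mean())

    @property
    def mean_r_squared_percent(self) -> float:
        return float(100.0 * self.r_squareds.mean())


def replicate_recovery(
    time_point: str,
    phenotype: str,
    *,
    predictor: str = "combined",
    effects: str = "equal_combined",
    n_replicates: int = 200,
    seed: int = 0,
    stream: int = 0,
    cohort_size: int | None = None,
) -> RecoveryStudy:
    """Simulate ``n_replicates`` cohorts at a table row and fit one predictor.

    ``predictor`` is ``"combined"`` (unweighted 2-SNP T-allele score) or one
    of the rsids. Each replicate draws the row's analysed N (unless
    ``cohort_size`` overrides it) and its own seeded substream derived from
    ``(seed, stream, replicate)``.
    """
    sc = scenario_from_table(time_point, phenotype)
    q1, q2 = EFFECT_ALLELE_FREQS[VARIANT_IDS[0]], EFFECT_ALLELE_FREQS[VARIANT_IDS[1]]
    if effects == "equal_combined":
        beta1 = beta2 = sc.beta_combined
    elif effects == "per_snp":
        beta1, beta2 = sc.beta_rs2472297, sc.beta_rs6968865
    else:
        raise ValueError(f"unknown effects parameterization {effects!r}")
    n = cohort_size if cohort_size is not None else sc.n

    betas = np.empty(n_replicates)
    ses = np.empty(n_replicates)
    r2s = np.empty(n_replicates)
    for i in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(stream), i)))
        g1, _ = simulate_genotypes(n, q1, rng=rng)
        g2, _ = simulate_genotypes(n, q2, rng=rng)
        y = simulate_trait(
            g1, g2, mean=sc.mean, sd=sc.sd, beta1=beta1, beta2=beta2, q1=q1, q2=q2, rng=rng
        )
        if predictor == "combined":
            x = g1 + g2
        elif predictor == VARIANT_IDS[0]:
            x = g1
        elif predictor == VARIANT_IDS[1]:
            x = g2
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        fit = ols_additive(y, x)
        betas[i], ses[i], r2s[i] = fit.beta, fit.se, fit.r_squared
    return RecoveryStudy(
        scenario=sc, predictor=predictor, effects=effects, betas=betas, ses=ses, r_squareds=r2s
    )
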