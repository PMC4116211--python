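"""Replicate parameter recovery at the 145-month total-caffeine parameterization.

Simulates 200 cohorts of n = 4,460 at the reference generating values
(phenotype SD 144.9 mg, T-allele frequencies 0.27 / 0.61, equal per-SNP
effects at the combined-score coefficient 17.1 mg per T allele), fits the
combined-score OLS per cohort, and summarizes the replicate distribution.
"""

from caffscore.recovery import replicate_recovery

study = replicate_recovery(
    "145mo", "total", predictor="combined", effects="equal_combined",
    n_replicates=200, seed=1, stream=1,
)

sc = study.scenario
print(f"scenario: n={sc.n}, mean={sc.mean} mg, SD={sc.sd} mg, "
      f"generating combined beta={sc.beta_combined} mg per T allele")
print(f"replicates: {study.n_replicates}")
print(f"mean fitted beta: {study.mean_beta:.2f} mg per T allele "
      f"(Monte-Carlo SE {study.mc_se:.3f})")
print(f"mean fitted SE:   {study.mean_se:.2f}  (reference row SE: {sc.se_combined})")
print(f"mean R^2:         {study.mean_r_squared_percent:.2f}% of phenotypic variance")
print()
print("The replicate mean sits on the generating coefficient and the average")
print("standard error reproduces the row's SE, so at this cohort size the 2-SNP")
print("score explains roughly 1.2% of the variance in daily caffeine intake.")
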