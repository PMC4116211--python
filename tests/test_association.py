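"""Additive OLS models, variance explained, non-additivity, and the sweep."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from caffscore import (
    association_sweep,
    dominance_test,
    interaction_test,
    ols_additive,
    scenario_from_table,
    variance_explained_analytic,
    zero_consumer_sensitivity,
)
from caffscore.association import hwe_score_variance
from caffscore.simulate import simulate_genotypes, simulate_trait


class TestOLSAdditive:
    def test_perfect_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r = ols_additive(2 * x, x)
        assert r.beta == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_closed_form_slope_example(self):
        r = ols_additive([1.0, 2.0, 4.0], [0.0, 1.0, 2.0])
        assert r.beta == pytest.approx(1.5)

    def test_constant_response(self):
        r = ols_additive([5.0, 5.0, 5.0, 5.0], [0.0, 1.0, 2.0, 1.0])
        assert r.beta == 0.0
        assert r.r_squared == 0.0

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3 complete"):
            ols_additive([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="monomorphic"):
            ols_additive([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_complete_case_dropping(self):
        r = ols_additive([1.0, 2.0, 4.0, np.nan], [0.0, 1.0, 2.0, 2.0])
        assert r.n == 3 and r.beta == pytest.approx(1.5)

    def test_matches_statsmodels(self, rng):
        x = rng.integers(0, 5, size=200).astype(float)
        y = 1.5 + 0.8 * x + rng.normal(0, 2, size=200)
        mine = ols_additive(y, x)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert mine.beta == pytest.approx(ref.params[1], rel=1e-10)
        assert mine.se == pytest.approx(ref.bse[1], rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalues[1], rel=1e-8)
        assert mine.r_squared == pytest.approx(ref.rsquared, rel=1e-10)

    @given(shift=st.floats(-100, 100), scale=st.floats(0.1, 50))
    def test_equivariance(self, shift, scale):
        rng = np.random.default_rng(99)
        x = rng.integers(0, 5, size=80).astype(float)
        y = 2.0 * x + rng.normal(0, 1, size=80)
        base = ols_additive(y, x)
        shifted = ols_additive(y + shift, x)
        assert shifted.beta == pytest.approx(base.beta, rel=1e-9, abs=1e-9)
        scaled = ols_additive(y * scale, x)
        assert scaled.beta == pytest.approx(base.beta * scale, rel=1e-9)
        assert scaled.se == pytest.approx(base.se * scale, rel=1e-9)

    def test_r2_equals_analytic_identity(self, rng):
        """For simple OLS, R^2 == beta^2 var(x)/var(y) at the fitted beta."""
        x = rng.integers(0, 5, size=500).astype(float)
        y = 0.6 * x + rng.normal(0, 1.5, size=500)
        r = ols_additive(y, x)
        analytic = variance_explained_analytic(r.beta, np.var(x), np.var(y))
        assert r.r_squared == pytest.approx(analytic, rel=1e-10)


class TestVarianceExplained:
    def test_null_and_identity_limits(self):
        assert variance_explained_analytic(0.0, 0.4, 100.0) == 0.0
        assert variance_explained_analytic(1.0, 7.0, 7.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            variance_explained_analytic(1.0, 0.0, 1.0)

    def test_single_snp_hwe_value_matches_large_simulation(self, rng):
        """Analytic per-SNP R^2 from the packaged 145-mo constants vs empirical R^2."""
        sc = scenario_from_table("145mo", "total")
        q = 0.27
        analytic = variance_explained_analytic(
            sc.beta_rs2472297, hwe_score_variance(q), sc.sd**2
        )
        g1, _ = simulate_genotypes(150_000, q, rng=rng)
        g2, _ = simulate_genotypes(150_000, 0.61, rng=rng)
        y = simulate_trait(
            g1, g2, mean=sc.mean, sd=sc.sd, beta1=sc.beta_rs2472297, beta2=0.0,
            q1=q, q2=0.61, rng=rng,
        )
        empirical = ols_additive(y, g1).r_squared
        assert empirical == pytest.approx(analytic, rel=0.15)


class TestNonAdditivity:
    def test_additive_truth_noiseless(self, rng):
        g = rng.integers(0, 3, size=300).astype(float)
        r = dominance_test(3.0 + 2.0 * g, g)
        assert abs(r.term_estimate) < 1e-9
        assert r.p_value == 1.0

    def test_pure_dominance_detected(self, rng):
        g = rng.integers(0, 3, size=400).astype(float)
        y = (g == 1).astype(float) + rng.normal(0, 0.05, size=400)
        r = dominance_test(y, g)
        assert r.term_estimate == pytest.approx(1.0, abs=0.05)
        assert r.p_value < 1e-10

    def test_missing_genotype_class_rejected(self):
        with pytest.raises(ValueError, match="2"):
            dominance_test([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, 1.0])

    def test_dominance_matches_statsmodels(self, rng):
        g = rng.integers(0, 3, size=250).astype(float)
        y = 1.0 + 0.5 * g + 0.3 * (g == 1) + rng.normal(0, 1, size=250)
        mine = dominance_test(y, g)
        X = sm.add_constant(np.column_stack([g, (g == 1).astype(float)]))
        ref = sm.OLS(y, X).fit()
        assert mine.term_estimate == pytest.approx(ref.params[2], rel=1e-9)
        assert mine.term_se == pytest.approx(ref.bse[2], rel=1e-9)
        assert mine.p_value == pytest.approx(ref.pvalues[2], rel=1e-7)

    def test_additive_two_locus_truth_noiseless(self, rng):
        g1 = rng.integers(0, 3, size=300).astype(float)
        g2 = rng.integers(0, 3, size=300).astype(float)
        r = interaction_test(1.0 + 2.0 * g1 - 0.7 * g2, g1, g2)
        assert abs(r.term_estimate) < 1e-9
        assert r.p_value == 1.0

    def test_pure_epistasis_detected(self, rng):
        g1 = rng.integers(0, 3, size=400).astype(float)
        g2 = rng.integers(0, 3, size=400).astype(float)
        r = interaction_test(g1 * g2 + rng.normal(0, 0.05, size=400), g1, g2)
        assert r.term_estimate == pytest.approx(1.0, abs=0.05)
        assert r.p_value < 1e-10

    def test_interaction_matches_statsmodels(self, rng):
        g1 = rng.integers(0, 3, size=250).astype(float)
        g2 = rng.integers(0, 3, size=250).astype(float)
        y = 0.5 * g1 + 0.2 * g2 + 0.15 * g1 * g2 + rng.normal(0, 1, size=250)
        mine = interaction_test(y, g1, g2)
        X = sm.add_constant(np.column_stack([g1, g2, g1 * g2]))
        ref = sm.OLS(y, X).fit()
        assert mine.term_estimate == pytest.approx(ref.params[3], rel=1e-9)
        assert mine.term_se == pytest.approx(ref.bse[3], rel=1e-9)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            interaction_test([1.0, 2.0, 3.0, 4.0, 5.0],
                             [1.0, 1.0, 1.0, 1.0, 1.0],
                             [0.0, 1.0, 2.0, 0.0, 1.0])


def test_mean_fitted_se_matches_analytic(rng):
    """Mean OLS SE ~= sigma_resid / (sqrt(n) * sd(score)) at large n."""
    sc = scenario_from_table("145mo", "total")
    n, reps = 5000, 40
    ses, analytic = [], []
    for _ in range(reps):
        g1, _ = simulate_genotypes(n, 0.27, rng=rng)
        g2, _ = simulate_genotypes(n, 0.61, rng=rng)
        score = g1 + g2
        y = simulate_trait(
            g1, g2, mean=sc.mean, sd=sc.sd, beta1=sc.beta_combined, beta2=sc.beta_combined,
            q1=0.27, q2=0.61, rng=rng,
        )
        fit = ols_additive(y, score)
        ses.append(fit.se)
        resid_sd = np.sqrt(sc.sd**2 - sc.beta_combined**2 * (2 * 0.27 * 0.73 + 2 * 0.61 * 0.39))
        analytic.append(resid_sd / (np.sqrt(n) * score.std()))
    assert np.mean(ses) == pytest.approx(np.mean(analytic), rel=0.02)


class TestAssociationSweep:
    def test_counting_contract(self, small_cohort):
        from caffscore import build_phenotype_table

        phenos = build_phenotype_table(small_cohort.observations)
        sweep = association_sweep(phenos, small_cohort.genotypes)
        # 8 time points x 4 phenotypes x 3 predictors
        assert len(sweep) == 96
        assert list(sweep.columns[:8]) == [
            "phenotype", "time_point", "predictor", "n", "beta", "se", "p_value", "r_squared",
        ]
        # deterministic ordering: time-major, then phenotype, then predictor
        assert sweep["time_point"].iloc[0] == "8wk" and sweep["time_point"].iloc[-1] == "145mo"

    def test_dropping_cola_leaves_other_cells_unchanged(self, small_cohort):
        from caffscore import build_phenotype_table

        phenos = build_phenotype_table(small_cohort.observations)
        full = association_sweep(phenos, small_cohort.genotypes)
        no_cola = association_sweep(
            phenos.assign(cola_per_day=np.nan), small_cohort.genotypes
        )
        assert not (no_cola["phenotype"] == "cola").any()
        a = full[full["phenotype"] == "tea"].reset_index(drop=True)
        b = no_cola[no_cola["phenotype"] == "tea"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_join_rejected(self, small_cohort):
        from caffscore import build_phenotype_table

        phenos = build_phenotype_table(small_cohort.observations)
        other = small_cohort.genotypes.copy()
        other.index = "X" + other.index
        with pytest.raises(ValueError, match="empty join"):
            association_sweep(phenos, other)

    def test_determinism(self, small_cohort):
        from caffscore import build_phenotype_table

        phenos = build_phenotype_table(small_cohort.observations)
        a = association_sweep(phenos, small_cohort.genotypes)
        b = association_sweep(phenos, small_cohort.genotypes)
        pd.testing.assert_frame_equal(a, b)


class TestZeroConsumerSensitivity:
    def _phenos(self, y, subjects):
        return pd.DataFrame(
            {
                "subject_id": subjects,
                "time_point": "8wk",
                "coffee_per_day": y,
                "tea_per_day": np.nan,
                "cola_per_day": np.nan,
                "total_caffeine_mg": np.nan,
            }
        )

    def test_all_positive_equals_full_sweep(self, rng):
        n = 400
        g1, _ = simulate_genotypes(n, 0.27, rng=rng)
        g2, _ = simulate_genotypes(n, 0.61, rng=rng)
        geno = pd.DataFrame(
            {"rs2472297": g1, "rs6968865": g2},
            index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
        )
        y = 2.0 + rng.normal(0, 0.1, size=n)  # strictly positive
        phenos = self._phenos(y, geno.index)
        full = association_sweep(phenos, geno)
        sens = zero_consumer_sensitivity(phenos, geno)
        pd.testing.assert_frame_equal(full, sens)

    def test_genotype_independent_zeros_leave_beta_unbiased(self, rng):
        """Excluding zero consumers at random shifts betas by < 2 MC SE."""
        reps, n, beta_true = 60, 1500, 0.2
        diffs = []
        for _ in range(reps):
            g1, _ = simulate_genotypes(n, 0.27, rng=rng)
            g2, _ = simulate_genotypes(n, 0.61, rng=rng)
            y = 3.0 + beta_true * (g1 + g2) + rng.normal(0, 1.5, size=n)
            zero = rng.random(n) < 0.15  # zeros independent of genotype
            y = np.where(zero, 0.0, np.maximum(y, 0.01))
            geno = pd.DataFrame(
                {"rs2472297": g1, "rs6968865": g2},
                index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
            )
            phenos = self._phenos(y, geno.index)
            full = association_sweep(phenos, geno, predictors=("combined",))
            sens = zero_consumer_sensitivity(phenos, geno, predictors=("combined",))
            diffs.append(sens["beta"].iloc[0] - full["beta"].iloc[0])
        # exclusion-induced shift is noise around the zero-handling difference
        assert abs(np.mean(diffs)) < 2 * np.std(diffs) / np.sqrt(reps) + 0.05

    def test_all_zero_beverage_flagged_not_fatal(self, rng):
        n = 50
        g1, _ = simulate_genotypes(n, 0.27, rng=rng)
        g2, _ = simulate_genotypes(n, 0.61, rng=rng)
        geno = pd.DataFrame(
            {"rs2472297": g1, "rs6968865": g2},
            index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
        )
        phenos = self._phenos(np.zeros(n), geno.index)
        sens = zero_consumer_sensitivity(phenos, geno)
        assert sens.empty
        assert len(sens.attrs["skipped"]) > 0
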