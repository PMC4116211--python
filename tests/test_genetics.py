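"""Genotype QC, best-guess calling, allelic scores and file ingestion."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caffscore import (
    QCThresholds,
    VariantData,
    best_guess,
    combined_score,
    effect_allele_frequency,
    hwe_exact_test,
    qc_filter,
    read_dosage_tsv,
    read_vcf,
)
from caffscore.genetics import filter_individuals, write_dosage_tsv
from caffscore.simulate import simulate_genotypes


def hwe_exact_oracle(n_ref_hom, n_het, n_alt_hom):
    """Independent exact-rational enumeration of the conditional HWE test."""
    n = n_ref_hom + n_het + n_alt_hom
    na = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    if na == 0:
        return Fraction(1)
    total = 0
    weights = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        minor_hom = (na - h) // 2
        major_hom = n - h - minor_hom
        w = Fraction(2**h) * Fraction(
            comb(n, minor_hom) * comb(n - minor_hom, h)
        )
        weights[h] = w
        total += w
    p_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= p_obs) / total


class TestEffectAlleleFrequency:
    @pytest.mark.parametrize(
        "calls,expected",
        [([0, 1, 2], 0.5), ([2, 2, 2, 2], 1.0), ([1, 1, 0, 0], 0.25)],
    )
    def test_examples(self, calls, expected):
        assert effect_allele_frequency(calls) == pytest.approx(expected)

    def test_missing_ignored_and_all_missing_rejected(self):
        assert effect_allele_frequency([1, np.nan, 1]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            effect_allele_frequency([np.nan, np.nan])

    def test_non_hard_calls_rejected(self):
        with pytest.raises(ValueError):
            effect_allele_frequency([0.5, 1])

    def test_converges_to_simulated_frequency(self, rng):
        q, n = 0.27, 50_000
        calls, _ = simulate_genotypes(n, q, rng=rng)
        assert abs(effect_allele_frequency(calls) - q) <= 3 * np.sqrt(q * (1 - q) / (2 * n))


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(17, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 9) == 1.0

    @pytest.mark.parametrize("config", [(0, 2, 0), (1, 0, 1), (25, 50, 25), (5, 1, 5)])
    def test_matches_exact_rational_oracle(self, config):
        assert hwe_exact_test(*config) == pytest.approx(float(hwe_exact_oracle(*config)), rel=1e-9)

    def test_extreme_departure_is_small(self):
        # all-heterozygote and no-heterozygote samples at intermediate freq
        assert hwe_exact_test(0, 100, 0) < 1e-20
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    def test_p_in_unit_interval(self, a, h, b):
        if a + h + b == 0:
            return
        p = hwe_exact_test(a, h, b)
        assert 0.0 < p <= 1.0


class TestBestGuess:
    @pytest.mark.parametrize(
        "dosage,expected",
        [(0.96 * 2, 2), (1.0, 1), (0.5, 1), (0.49, 0), (1.49, 1), (1.5, 2), (0.0, 0), (2.0, 2)],
    )
    def test_half_open_bins(self, dosage, expected):
        assert best_guess(dosage) == expected

    def test_vectorized_with_missing(self):
        out = best_guess(np.array([0.2, np.nan, 1.8]))
        assert out[0] == 0 and np.isnan(out[1]) and out[2] == 2

    @pytest.mark.parametrize("bad", [-0.01, 2.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            best_guess(bad)


def _variant_from_freq(rsid, q, n=2000, call_rate=1.0, seed=5, hwe_break=False):
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, q, size=n).astype(float)
    if hwe_break:  # all hets -> gross HWE violation
        calls = np.ones(n)
    n_missing = int(round((1 - call_rate) * n))
    if n_missing:
        calls[:n_missing] = np.nan
    return VariantData(variant_id=rsid, effect_allele="T", hard_calls=calls)


class TestQCFilter:
    def test_clean_variant_kept(self):
        v = _variant_from_freq("rs2472297", 0.27)
        kept, reasons = qc_filter([v])
        assert kept == ["rs2472297"] and reasons == {}

    def test_all_fail_reasons_enumerated(self):
        v = _variant_from_freq("rsBad", 0.004, call_rate=0.90)
        kept, reasons = qc_filter([v])
        assert kept == []
        joined = " ".join(reasons["rsBad"])
        assert "maf" in joined and "call_rate" in joined

    def test_hwe_failure_reported(self):
        v = _variant_from_freq("rsHet", 0.5, hwe_break=True)
        _, reasons = qc_filter([v])
        assert any("hwe" in r for r in reasons["rsHet"])

    @given(
        maf_min=st.floats(0.001, 0.2),
        call_rate_min=st.floats(0.5, 0.999),
        relax=st.floats(0.0, 0.5),
    )
    def test_monotone_in_thresholds(self, maf_min, call_rate_min, relax):
        variants = [
            _variant_from_freq("a", 0.27),
            _variant_from_freq("b", 0.05, call_rate=0.93),
            _variant_from_freq("c", 0.02, call_rate=0.97),
        ]
        strict = QCThresholds(maf_min=maf_min, call_rate_min=call_rate_min)
        loose = QCThresholds(
            maf_min=maf_min * (1 - relax), call_rate_min=call_rate_min * (1 - relax)
        )
        kept_strict, _ = qc_filter(variants, strict)
        kept_loose, _ = qc_filter(variants, loose)
        assert set(kept_strict) <= set(kept_loose)

    def test_individual_filter_runs_before_metrics(self):
        geno = pd.DataFrame(
            {"rs2472297": [1, np.nan, 0, 1], "rs6968865": [2, np.nan, 1, 1]},
            index=["a", "b", "c", "d"],
        )
        kept, dropped = filter_individuals(geno, 0.05)
        assert dropped == ["b"]
        assert list(kept.index) == ["a", "c", "d"]


class TestCombinedScore:
    def test_examples(self):
        assert combined_score(np.array([2.0]), np.array([2.0]))[0] == 4.0
        weighted = combined_score(np.array([1.0]), np.array([1.0]), weights=(0.31, 0.26))
        assert weighted[0] == pytest.approx(0.57)
        assert np.isnan(combined_score(np.array([0.0]), np.array([np.nan]))[0])

    def test_misaligned_series_rejected(self):
        s1 = pd.Series([1.0, 2.0], index=["a", "b"])
        s2 = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError, match="misaligned"):
            combined_score(s1, s2)

    @given(st.lists(st.tuples(st.sampled_from([0, 1, 2]), st.sampled_from([0, 1, 2])), min_size=1))
    def test_unit_weights_equal_unweighted(self, pairs):
        g1 = np.array([p[0] for p in pairs], dtype=float)
        g2 = np.array([p[1] for p in pairs], dtype=float)
        np.testing.assert_array_equal(
            combined_score(g1, g2), combined_score(g1, g2, weights=(1.0, 1.0))
        )
        assert set(combined_score(g1, g2)) <= {0.0, 1.0, 2.0, 3.0, 4.0}


class TestFileIngestion:
    def test_dosage_tsv_roundtrip(self, tmp_path):
        geno = pd.DataFrame(
            {"rs2472297": [0.0, 1.2, np.nan], "rs6968865": [2.0, 0.4, 1.0]},
            index=pd.Index(["s1", "s2", "s3"], name="subject_id"),
        )
        path = tmp_path / "dos.tsv"
        write_dosage_tsv(geno, path)
        back = read_dosage_tsv(path)
        pd.testing.assert_frame_equal(back, geno)

    def test_allele_mismatch_is_error_not_flip(self, tmp_path):
        path = tmp_path / "dos.tsv"
        path.write_text("subject_id\trs2472297_G\ns1\t1.0\n")
        with pytest.raises(ValueError, match="rs2472297_G"):
            read_dosage_tsv(path)

    def test_out_of_range_dosage_rejected(self, tmp_path):
        path = tmp_path / "dos.tsv"
        path.write_text("subject_id\trs2472297_T\ns1\t2.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_dosage_tsv(path)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=7>
##contig=<ID=15>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
7\t17284577\trs6968865\tT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
15\t75027880\trs2472297\tC\tT\t.\tPASS\t.\tGT:DS\t0/1:1.10\t1/1:1.90\t0/0:0.20
"""


class TestVCFReader:
    def test_ds_used_and_ref_effect_allele_flipped(self, tmp_path):
        path = tmp_path / "variants.vcf"
        path.write_text(VCF_TEXT)
        dose = read_vcf(path, ["rs2472297", "rs6968865"])
        # rs2472297: ALT is T -> DS taken as-is
        np.testing.assert_allclose(dose["rs2472297"], [1.1, 1.9, 0.2], atol=1e-6)
        # rs6968865: REF is T -> dose explicitly flipped from ALT counts 1,0,2
        np.testing.assert_allclose(dose["rs6968865"], [1.0, 2.0, 0.0])
        assert list(dose.index) == ["S1", "S2", "S3"]

    def test_missing_rsid_rejected(self, tmp_path):
        path = tmp_path / "variants.vcf"
        path.write_text(VCF_TEXT)
        with pytest.raises(ValueError, match="rs999"):
            read_vcf(path, ["rs2472297", "rs999"])

    def test_effect_allele_absent_rejected(self, tmp_path):
        path = tmp_path / "variants.vcf"
        path.write_text(VCF_TEXT.replace("15\t75027880\trs2472297\tC\tT", "15\t75027880\trs2472297\tC\tG"))
        with pytest.raises(ValueError, match="neither"):
            read_vcf(path, ["rs2472297"])
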