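"""Genotype ingestion, QC and allelic-score construction for the two caffeine loci.

Genotypes are coded as counts of the effect (T) allele at rs2472297 and
rs6968865. QC follows standard GWAS practice: variants are dropped on minor
allele frequency < 1%, call rate < 95%, or failure of an exact
Hardy-Weinberg equilibrium test at p <= 5e-6; individuals with > 5% missing
genotypes are removed first. The 2-SNP allelic score is the per-subject sum
of T-allele counts, optionally weighted by published per-allele effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .constants import EFFECT_ALLELE, QCThresholds, SCORE_WEIGHTS, VARIANT_IDS


def effect_allele_frequency(calls: Sequence[float]) -> float:
    """Effect-allele frequency from hard calls in {0, 1, 2}; NaN = missing."""
    arr = np.asarray(calls, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        raise ValueError("no non-missing genotype calls")
    if not np.isin(valid, (0.0, 1.0, 2.0)).all():
        bad = np.unique(valid[~np.isin(valid, (0.0, 1.0, 2.0))])
        raise ValueError(f"calls must be in {{0,1,2}}, found {bad}")
    return float(valid.sum() / (2.0 * valid.size))


def hwe_exact_test(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Two-sided exact test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and enumerates every attainable
    heterozygote count, weighting each configuration by the number of
    distinct genotype assignments producing it. The p-value is the total
    probability of configurations no more probable than the observed one, so
    it lies in (0, 1] and is 1 for monomorphic samples.
    """
    counts = (n_ref_hom, n_het, n_alt_hom)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("empty sample")
    n_minor = min(2 * n_ref_hom + n_het, 2 * n_alt_hom + n_het)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log multiplicity of each configuration given the allele counts:
    # 2^h * n! / (minor_hom! * h! * major_hom!)
    minor_hom = (n_minor - hets) // 2
    major_hom = n - hets - minor_hom
    logw = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(minor_hom + 1)
        - gammaln(hets + 1)
        - gammaln(major_hom + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def best_guess(dosage):
    """Round an imputed dosage in [0, 2] to a hard call in {0, 1, 2}.

    Bins are half-open: [0, 0.5) -> 0, [0.5, 1.5) -> 1, [1.5, 2] -> 2.
    Missing (NaN) dosages stay missing. Accepts scalars or arrays.
    """
    arr = np.asarray(dosage, dtype=float)
    valid = ~np.isnan(arr)
    if ((arr < 0) & valid).any() or ((arr > 2) & valid).any():
        raise ValueError(f"dosage outside [0, 2]: {np.asarray(dosage)}")
    out = np.where(arr < 0.5, 0.0, np.where(arr < 1.5, 1.0, 2.0))
    out = np.where(valid, out, np.nan)
    if np.isscalar(dosage) or np.ndim(dosage) == 0:
        return float(out)
    return out


@dataclass
class VariantData:
    """Per-variant effect-allele calls plus derived QC metrics."""

    variant_id: str
    effect_allele: str
    hard_calls: np.ndarray  # float array; NaN = missing
    dosages: np.ndarray | None = None
    imputation_quality: float | None = None
    effect_allele_freq: float = field(init=False)
    maf: float = field(init=False)
    call_rate: float = field(init=False)
    hwe_p: float = field(init=False)

    def __post_init__(self) -> None:
        calls = np.asarray(self.hard_calls, dtype=float)
        self.hard_calls = calls
        self.call_rate = float(np.mean(~np.isnan(calls)))
        self.effect_allele_freq = effect_allele_frequency(calls)
        self.maf = float(min(self.effect_allele_freq, 1.0 - self.effect_allele_freq))
        valid = calls[~np.isnan(calls)]
        self.hwe_p = hwe_exact_test(
            int((valid == 0).sum()), int((valid == 1).sum()), int((valid == 2).sum())
        )

    @classmethod
    def from_dosages(
        cls,
        variant_id: str,
        dosages: Sequence[float],
        *,
        effect_allele: str = EFFECT_ALLELE,
        imputation_quality: float | None = None,
    ) -> "VariantData":
        dos = np.asarray(dosages, dtype=float)
        return cls(
            variant_id=variant_id,
            effect_allele=effect_allele,
            hard_calls=best_guess(dos),
            dosages=dos,
            imputation_quality=imputation_quality,
        )


def filter_individuals(
    genotypes: pd.DataFrame, max_missingness: float = QCThresholds().individual_missingness_max
) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose missing-genotype fraction exceeds the threshold.

    Applied before variant-level metrics so failing subjects do not distort
    call rates or HWE. Returns (kept table, dropped subject ids).
    """
    frac_missing = genotypes.isna().mean(axis=1)
    dropped = genotypes.index[frac_missing > max_missingness].tolist()
    return genotypes.drop(index=dropped), dropped


def qc_filter(
    variants: Iterable[VariantData], thresholds: QCThresholds = QCThresholds()
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply variant-level QC; every failed criterion is reported, not just the first.

    Keeps a variant iff maf >= maf_min AND call_rate >= call_rate_min AND
    hwe_p > hwe_p_min.
    """
    kept: list[str] = []
    reasons: dict[str, list[str]] = {}
    for v in variants:
        fails = []
        if v.maf < thresholds.maf_min:
            fails.append(f"maf {v.maf:.4g} < {thresholds.maf_min}")
        if v.call_rate < thresholds.call_rate_min:
            fails.append(f"call_rate {v.call_rate:.4g} < {thresholds.call_rate_min}")
        if not v.hwe_p > thresholds.hwe_p_min:
            fails.append(f"hwe_p {v.hwe_p:.3g} <= {thresholds.hwe_p_min}")
        if fails:
            reasons[v.variant_id] = fails
        else:
            kept.append(v.variant_id)
    return kept, reasons


def combined_score(calls_snp1, calls_snp2, weights: Mapping[str, float] | Sequence[float] | None = None):
    """Per-subject allelic score across the two SNPs.

    Unweighted (default): total T-allele count g1 + g2 in {0..4}. Weighted:
    w1*g1 + w2*g2. The score is missing wherever either genotype is missing.
    pandas Series inputs must carry identical subject indexes; mismatches are
    an error, not an implicit intersection.
    """
    if isinstance(calls_snp1, pd.Series) and isinstance(calls_snp2, pd.Series):
        only1 = calls_snp1.index.difference(calls_snp2.index)
        only2 = calls_snp2.index.difference(calls_snp1.index)
        if len(only1) or len(only2):
            raise ValueError(
                "misaligned subject sets: "
                f"{list(only1[:5])} only in SNP1, {list(only2[:5])} only in SNP2"
            )
        calls_snp2 = calls_snp2.reindex(calls_snp1.index)
        g1, g2 = calls_snp1.astype(float), calls_snp2.astype(float)
    else:
        g1 = np.asarray(calls_snp1, dtype=float)
        g2 = np.asarray(calls_snp2, dtype=float)
        if g1.shape != g2.shape:
            raise ValueError(f"misaligned call vectors: shapes {g1.shape} vs {g2.shape}")
    for g in (g1, g2):
        vals = np.asarray(g, dtype=float)
        vals = vals[~np.isnan(vals)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype calls must be hard calls in {0,1,2}")
    if weights is None:
        return g1 + g2
    if isinstance(weights, Mapping):
        w1, w2 = weights[VARIANT_IDS[0]], weights[VARIANT_IDS[1]]
    else:
        w1, w2 = weights
    return w1 * g1 + w2 * g2


def weighted_score(calls_snp1, calls_snp2):
    """Allelic score weighted by the published per-allele effects (0.31, 0.26)."""
    return combined_score(calls_snp1, calls_snp2, weights=SCORE_WEIGHTS)


# ---------------------------------------------------------------------------
# file ingestion


def read_dosage_tsv(path, *, effect_allele: str = EFFECT_ALLELE) -> pd.DataFrame:
    """Read an additive-dosage TSV (PLINK .raw dialect for the dosage columns).

    Header is ``subject_id`` followed by one column per variant named
    ``<rsid>_<counted allele>``; values in [0, 2], empty = missing. A counted
    allele other than the configured effect allele is an error — alleles are
    never silently flipped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, na_values=[""])
    if "subject_id" not in df.columns:
        raise ValueError("dosage TSV must have a subject_id column")
    rename = {}
    for col in df.columns:
        if col == "subject_id":
            continue
        rsid, _, allele = col.rpartition("_")
        if not rsid:
            raise ValueError(f"dosage column {col!r} is not of the form <rsid>_<allele>")
        if allele != effect_allele:
            raise ValueError(
                f"column {col!r} counts allele {allele!r} but the configured "
                f"effect allele is {effect_allele!r}; refusing to flip silently"
            )
        rename[col] = rsid
    out = df.rename(columns=rename).set_index("subject_id")
    bad = [(c, float(out[c].min()), float(out[c].max()))
           for c in out.columns
           if ((out[c] < 0) | (out[c] > 2)).any()]
    if bad:
        raise ValueError(f"dosages outside [0,2] in columns: {bad}")
    return out.astype(float)


def read_vcf(path, rsids: Sequence[str] = VARIANT_IDS, *, effect_allele: str = EFFECT_ALLELE) -> pd.DataFrame:
    """Extract effect-allele dosages for the configured rsids from a VCF.

    Uses the DS FORMAT field when present, else counts ALT alleles from GT.
    If the effect allele is the REF allele at a site, the dose is explicitly
    flipped (2 - alt_dose); if it is neither REF nor ALT, that is an error.
    Requires cyvcf2 (``pip install caffscore[vcf]``).
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = set(rsids)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        if variant.ID not in wanted:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"{variant.ID}: multi-allelic sites are not supported")
        alt = variant.ALT[0]
        ds = variant.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(variant.genotype.array(), dtype=float)[:, :2]
            gts[gts < 0] = np.nan
            dose = gts.sum(axis=1)
        if effect_allele == alt:
            pass
        elif effect_allele == variant.REF:
            dose = 2.0 - dose
        else:
            raise ValueError(
                f"{variant.ID}: effect allele {effect_allele!r} is neither "
                f"REF ({variant.REF!r}) nor ALT ({alt!r})"
            )
        data[variant.ID] = dose
    missing = wanted - set(data)
    if missing:
        raise ValueError(f"rsids not found in VCF: {sorted(missing)}")
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))[list(rsids)]


def write_dosage_tsv(genotypes: pd.DataFrame, path, *, effect_allele: str = EFFECT_ALLELE) -> None:
    out = genotypes.copy()
    out.columns = [f"{c}_{effect_allele}" for c in out.columns]
    out.reset_index().rename(columns={out.index.name or "index": "subject_id"}).to_csv(
        path, sep="\t", index=False, na_rep=""
    )
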