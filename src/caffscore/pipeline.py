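"""End-to-end orchestration: refinement -> genotype QC -> score -> association -> validation.

``run_pipeline`` consumes the three input tables (long questionnaire
observations, additive genotype dosages, confounders), runs every stage with
reference defaults, and writes the full report bundle: association
tables for total caffeine, coffee, tea and cola; decaf negative-control
tables; confounder balance and phenotype-confounding tables; and a run log
recording versions, options, per-stage row counts and any QC exclusions.
Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import association_sweep, zero_consumer_sensitivity
from .constants import EFFECT_ALLELE, QCThresholds, VARIANT_IDS
from .genetics import VariantData, best_guess, filter_individuals, qc_filter, read_dosage_tsv
from .phenotype import build_phenotype_table, read_observations_tsv, write_phenotypes_tsv
from .report import TABLE_PHENOTYPES, render_association_table, render_table
from .validation import DECAF_COLUMNS, confounder_balance, negative_control, phenotype_confounding


class PipelineError(RuntimeError):
    """A stage rejected its input; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and analysis options for one pipeline run."""

    observations: Path
    dosages: Path
    confounders: Path
    outdir: Path
    weighted_score: bool = False
    zero_consumer: bool = False
    impute_zero_cola: bool = False
    seed: int | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    verbose: bool = True


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


@_stage("refine")
def _refine(config: RunConfig, log: list[str]) -> pd.DataFrame:
    obs = read_observations_tsv(config.observations)
    log.append(f"refine: {len(obs)} observation rows read from {config.observations}")
    phenos = build_phenotype_table(obs, impute_zero_cola=config.impute_zero_cola)
    log.append(f"refine: {len(phenos)} subject x time-point phenotype rows")
    return phenos


@_stage("genoqc")
def _genoqc(config: RunConfig, log: list[str]) -> pd.DataFrame:
    dosages = read_dosage_tsv(config.dosages)
    missing_cols = [v for v in VARIANT_IDS if v not in dosages.columns]
    if missing_cols:
        raise ValueError(f"dosage table missing variants: {missing_cols}")
    dosages, dropped = filter_individuals(dosages, config.qc.individual_missingness_max)
    log.append(
        f"genoqc: individual missingness filter (> {config.qc.individual_missingness_max:.0%}) "
        f"applied before variant metrics; dropped {len(dropped)} subjects"
    )
    calls = pd.DataFrame(
        {v: best_guess(dosages[v].to_numpy()) for v in VARIANT_IDS}, index=dosages.index
    )
    variants = [
        VariantData(variant_id=v, effect_allele=EFFECT_ALLELE, hard_calls=calls[v].to_numpy())
        for v in VARIANT_IDS
    ]
    kept, reasons = qc_filter(variants, config.qc)
    for v in variants:
        log.append(
            f"genoqc: {v.variant_id} T-freq {v.effect_allele_freq:.3f} maf {v.maf:.3f} "
            f"call_rate {v.call_rate:.4f} hwe_p {v.hwe_p:.3g} -> "
            + ("kept" if v.variant_id in kept else f"FAILED {reasons[v.variant_id]}")
        )
    if set(kept) != set(VARIANT_IDS):
        raise ValueError(f"variants failed QC: {reasons}")
    return calls


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns written paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"caffscore {__version__}", f"options: {config}"]
    if config.seed is not None:
        log.append(f"seed: {config.seed}")
    written: dict[str, Path] = {}

    phenos = _refine(config, log)
    calls = _genoqc(config, log)
    write_phenotypes_tsv(phenos, outdir / "phenotypes.tsv")
    written["phenotypes"] = outdir / "phenotypes.tsv"

    predictors = [VARIANT_IDS[0], VARIANT_IDS[1], "combined"]
    if config.weighted_score:
        predictors.append("weighted")

    @_stage("associate")
    def _associate():
        sweep = association_sweep(phenos, calls, predictors=predictors)
        log.append(f"associate: {len(sweep)} fitted cells, {len(sweep.attrs['skipped'])} skipped")
        return sweep

    sweep = _associate()
    for layout, phenotype in TABLE_PHENOTYPES.items():
        path = outdir / f"{layout}_{phenotype}.tsv"
        path.write_text(render_table(sweep, layout))
        written[layout] = path

    if config.zero_consumer:

        @_stage("associate-sensitivity")
        def _sensitivity():
            sens = zero_consumer_sensitivity(phenos, calls, predictors=predictors)
            for phenotype in TABLE_PHENOTYPES.values():
                path = outdir / f"sensitivity_{phenotype}_positive_only.tsv"
                path.write_text(render_association_table(sens, phenotype))
                written[f"sensitivity_{phenotype}"] = path
            log.append(f"associate-sensitivity: {len(sens)} fitted cells")

        _sensitivity()

    @_stage("validate")
    def _validate():
        conf = pd.read_csv(config.confounders, sep="\t", dtype={"subject_id": str})
        balance = confounder_balance(calls, conf, predictors=predictors)
        (outdir / "table5_confounder_balance.tsv").write_text(render_table(balance, "table5"))
        written["table5"] = outdir / "table5_confounder_balance.tsv"
        confounding = phenotype_confounding(phenos, conf)
        (outdir / "table6_phenotype_confounding.tsv").write_text(render_table(confounding, "table6"))
        written["table6"] = outdir / "table6_phenotype_confounding.tsv"
        decaf = negative_control(phenos, calls, predictors=predictors)
        for label in DECAF_COLUMNS:
            path = outdir / f"negative_control_{label}.tsv"
            path.write_text(render_association_table(decaf, label))
            written[label] = path
        flagged = int((~decaf["consistent_with_null"]).sum())
        log.append(
            f"validate: {len(balance)} balance cells, {len(confounding)} confounding cells, "
            f"{len(decaf)} decaf cells ({flagged} inconsistent with null at alpha=0.05)"
        )

    _validate()

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n")
    written["log"] = log_path
    if config.verbose:
        print("\n".join(log), file=sys.stderr)
    return written
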