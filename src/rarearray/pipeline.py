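"""End-to-end orchestration of the rare-variant QC workflow.

Stage order: calling -> (rare het adjustment || advanced normalization) ->
consolidation -> MAF-concordance filtering -> disease screening. Every stage
writes its outputs and audit tables under the configured output directory,
and a run manifest records the package version, seed and input digests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import rarearray
from rarearray import fileio
from rarearray.advnorm import AdvNormParams, estimate_plate_shifts, renormalize_and_recall
from rarearray.calling import CallingParams, call_genotypes, fit_clusters, summarize_signals
from rarearray.concordance import compute_array_maf, filter_by_concordance
from rarearray.config import PipelineConfig
from rarearray.consolidate import consolidate, summarize_adjustments
from rarearray.rarehet import RareHetParams, rare_het_adjust
from rarearray.screening import (
    bin_by_maf,
    evaluate_screening,
    export_validation_list,
    sample_negative_calls,
)
from rarearray.types import GenotypeMatrix

logger = logging.getLogger("rarearray")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory handles on everything a run produced."""

    output_dir: Path
    base: GenotypeMatrix
    final: GenotypeMatrix
    adjustment_summary: dict
    concordance: pd.DataFrame | None = None
    diagnostics: object = None
    screening: object = None
    artifacts: dict[str, Path] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write_resolved()

    p = config.params
    calling_params = CallingParams(
        epsilon=p.epsilon,
        prior_center=p.prior_center,
        prior_var=p.prior_var,
        prior_weight=p.prior_weight,
        confidence_threshold=p.confidence_threshold,
    )

    artifacts: dict[str, Path] = {}

    def save(name: str, writer, *args) -> Path:
        path = out_dir / name
        writer(*args, path)
        artifacts[name] = path
        return path

    # --- inputs
    intensities = _stage("read_inputs")(fileio.read_intensities)(config.inputs["intensities"])
    manifest = fileio.read_manifest(config.inputs["manifest"])
    annotation = fileio.read_annotation(config.inputs["annotation"])

    # --- calling
    @_stage("calling")
    def _call():
        summary = summarize_signals(intensities, annotation, epsilon=p.epsilon)
        model = fit_clusters(summary, manifest, calling_params)
        base = call_genotypes(summary, model, manifest, p.confidence_threshold)
        return summary, model, base

    summary, model, base = _call()
    save("genotypes_base.tsv", fileio.write_genotypes, base)
    logger.info("calling: %d probesets x %d samples", len(base.probesets), len(base.samples))

    # --- rare het adjustment
    if config.stages.rarehet:
        @_stage("rarehet")
        def _rh():
            return rare_het_adjust(base, summary, model, manifest, RareHetParams(d_max=p.d_max))

        calls_rh, rh_audit = _rh()
        save("rarehet_audit.tsv", fileio.write_tsv, rh_audit)
        logger.info(
            "rarehet: %d of %d het calls demoted",
            int((rh_audit["verdict"] == "demote_to_nocall").sum()),
            len(rh_audit),
        )
    else:
        calls_rh = base.copy()

    # --- advanced normalization
    if config.stages.advnorm:
        @_stage("advnorm")
        def _an():
            an_params = AdvNormParams(
                shift_threshold=p.shift_threshold,
                min_plate_n=p.min_plate_n,
                confidence_threshold=p.confidence_threshold,
            )
            shifts = estimate_plate_shifts(summary, base, manifest, an_params)
            return shifts, *renormalize_and_recall(summary, base, shifts, model, manifest, an_params)

        shifts, calls_an, an_audit = _an()
        save("plate_shifts.tsv", fileio.write_tsv, shifts)
        save("advnorm_audit.tsv", fileio.write_tsv, an_audit)
        logger.info(
            "advnorm: %d plate x probeset combinations flagged, %d calls changed",
            int(shifts["flagged"].sum()),
            len(an_audit),
        )
    else:
        calls_an = base.copy()

    # --- consolidation + adjustment accounting
    @_stage("consolidate")
    def _cons():
        final = consolidate(calls_rh, calls_an, base)
        summaries = {
            "combined": summarize_adjustments(base, final).as_dict(),
            "rarehet": summarize_adjustments(base, calls_rh).as_dict(),
            "advnorm": summarize_adjustments(base, calls_an).as_dict(),
        }
        return final, summaries

    final, summaries = _cons()
    save("genotypes_final.tsv", fileio.write_genotypes, final)
    (out_dir / "adjustment_summary.json").write_text(json.dumps(summaries, indent=2))
    artifacts["adjustment_summary.json"] = out_dir / "adjustment_summary.json"
    logger.info("consolidate: %s", summaries["combined"])

    fileio.write_vcf(final, annotation, out_dir / "genotypes_final.vcf", source=f"rarearray {rarearray.__version__}")
    artifacts["genotypes_final.vcf"] = out_dir / "genotypes_final.vcf"

    result = PipelineResult(
        output_dir=out_dir,
        base=base,
        final=final,
        adjustment_summary=summaries,
        artifacts=artifacts,
    )

    # --- concordance filter
    ref_maf = None
    retained_variants = pd.Index(final.probesets)
    if config.stages.concordance:
        @_stage("concordance")
        def _conc():
            ref = fileio.read_ref_maf(config.inputs["ref_maf"]).set_index("variant_id")["ref_maf"]
            array_maf = compute_array_maf(final)
            return ref, *filter_by_concordance(array_maf, ref, p.t_upper, p.t_lower)

        ref_maf, conc_results, diagnostics = _conc()
        save("concordance.tsv", lambda f, path: fileio.write_tsv(f, path, index=True), conc_results)
        (out_dir / "concordance_diagnostics.json").write_text(
            json.dumps(diagnostics.as_dict(), indent=2)
        )
        artifacts["concordance_diagnostics.json"] = out_dir / "concordance_diagnostics.json"
        retained_variants = conc_results.index[conc_results["verdict"] != "excluded"]
        result.concordance = conc_results
        result.diagnostics = diagnostics
        logger.info(
            "concordance: %d retained, %d excluded, %d indeterminate",
            diagnostics.n_retained,
            diagnostics.n_excluded,
            diagnostics.n_indeterminate,
        )
    elif "ref_maf" in config.inputs:
        ref_maf = fileio.read_ref_maf(config.inputs["ref_maf"]).set_index("variant_id")["ref_maf"]

    # --- screening
    if config.stages.screening:
        @_stage("screening")
        def _screen():
            if "panels" in config.inputs:
                panels = fileio.read_tsv(config.inputs["panels"], dtype=str)
            else:
                panels = fileio.panels_from_annotation(annotation)
            panels = panels[panels["variant_id"].isin(retained_variants)]
            if "gold_standard" in config.inputs:
                gold = fileio.read_gold_standard(config.inputs["gold_standard"])
            else:
                truth = fileio.read_truth(config.inputs["truth_dir"])
                gold = fileio.truth_gold_standard(truth)
            if ref_maf is None:
                raise ValueError("screening needs reference MAFs for binning")
            bins = bin_by_maf(final.probesets, ref_maf)
            worklist = export_validation_list(final, panels)
            negatives = sample_negative_calls(final, panels, p.npv_fraction, config.seed)
            report = evaluate_screening(worklist, gold, bins, negatives)
            return worklist, report

        worklist, report = _screen()
        save("validation_worklist.tsv", fileio.write_tsv, worklist)
        save(
            "screening_report.tsv",
            lambda f, path: fileio.write_tsv(f, path, index=True),
            report.table,
        )
        (out_dir / "screening_report.json").write_text(
            json.dumps(report.as_records(), indent=2)
        )
        artifacts["screening_report.json"] = out_dir / "screening_report.json"
        result.screening = report

    # --- run manifest
    digests = {
        name: fileio.sha256_file(path)
        for name, path in sorted(config.inputs.items())
        if Path(path).is_file()
    }
    run_manifest = {
        "version": rarearray.__version__,
        "seed": config.seed,
        "input_digests": digests,
        "outputs": sorted(artifacts),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return result
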