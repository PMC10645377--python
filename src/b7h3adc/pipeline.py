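"""End-to-end pipeline driver: score → classify → evaluate (plus the
optional dose-response, funnel and IHC stages), with provenance."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .classifier import ClassifierConfig, classify_models, evaluate_calls
from .dose_response import compute_nauc
from .expression import Scale, tmm_normalize
from .funnel import run_funnel
from .histology import summarize_tma
from .models import annotations_from_table
from .signatures import score_signatures, z_transform


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, thresholds and seed of a full pipeline run.

    Every threshold is echoed into the run's provenance block.
    """

    expression_path: str | None = None
    gmt_path: str | None = None
    annotations_path: str | None = None
    dose_response_path: str | None = None
    cohort_path: str | None = None
    ihc_path: str | None = None
    out_dir: str = "results"
    seed: int | None = None
    nauc_threshold: float = 0.75
    hscore_cutoff: float = 20.0
    repstress_z_threshold: float = 1.0
    min_tumor_content: float = 0.30
    ssgsea_alpha: float = 0.25

    def thresholds(self) -> dict:
        return {
            "nauc_responder_threshold": self.nauc_threshold,
            "hscore_cutoff": self.hscore_cutoff,
            "repstress_z_threshold": self.repstress_z_threshold,
            "min_tumor_content": self.min_tumor_content,
            "ssgsea_alpha": self.ssgsea_alpha,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; abort cleanly before writing any
    output if a referenced input is missing."""
    inputs = [p for p in (config.expression_path, config.gmt_path,
                          config.annotations_path, config.dose_response_path,
                          config.cohort_path, config.ihc_path) if p]
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    out_dir = Path(config.out_dir)
    results: dict = {}

    if config.expression_path and config.gmt_path:
        expr = io.read_expression(config.expression_path, Scale.RAW_COUNTS)
        _, log_cpm = tmm_normalize(expr)
        gene_sets = io.read_gmt(config.gmt_path)
        scores = z_transform(
            score_signatures(log_cpm, gene_sets, alpha=config.ssgsea_alpha))
        io.write_scores(scores, out_dir / "signature_scores.tsv")
        results["scores"] = scores

    if config.dose_response_path:
        by_model = io.read_dose_response(config.dose_response_path)
        rows = []
        for model_id, exps in sorted(by_model.items()):
            targeted = [e for e in exps if e.agent.value == "targeted"]
            control = [e for e in exps if e.agent.value == "control"]
            s = compute_nauc(targeted, control,
                             responder_threshold=config.nauc_threshold)
            rows.append({"model_id": model_id, "nauc_median": s.nauc_median,
                         "nauc_iqr": s.nauc_iqr, "ic50": s.ic50,
                         "maxr": s.maxr, "responder": s.responder.value})
        summary = pd.DataFrame(rows)
        io.atomic_write_text(out_dir / "dose_response_summary.tsv",
                             summary.to_csv(index=False, sep="\t"))
        results["dose_response"] = summary

    if config.annotations_path:
        table = pd.read_csv(config.annotations_path, sep="\t")
        annotations = annotations_from_table(table)
        calls = classify_models(
            annotations,
            ClassifierConfig(repstress_z_threshold=config.repstress_z_threshold))
        calls_table = pd.DataFrame(
            [{"model_id": c.model_id, "predicted": c.predicted.value,
              "rule_fired": c.rule_fired, "rationale": c.rationale}
             for c in calls])
        io.atomic_write_text(out_dir / "biomarker_calls.tsv",
                             calls_table.to_csv(index=False, sep="\t"))
        results["calls"] = calls
        results["evaluation"] = evaluate_calls(calls, annotations)

    if config.cohort_path:
        cohort = io.read_cohort(config.cohort_path)
        report = run_funnel(cohort, min_tumor_content=config.min_tumor_content)
        io.atomic_write_text(out_dir / "funnel.txt", report.to_text() + "\n")
        io.atomic_write_text(out_dir / "funnel.tsv",
                             report.to_frame().to_csv(index=False, sep="\t"))
        results["funnel"] = report

    if config.ihc_path:
        cores = io.read_ihc(config.ihc_path)
        summary = summarize_tma(cores, cutoff=config.hscore_cutoff)
        io.atomic_write_text(
            out_dir / "tma_summary.tsv",
            summary["table"].to_csv(index=False, sep="\t"))
        results["tma"] = summary

    io.write_provenance(out_dir / "provenance.json", seed=config.seed,
                        thresholds=config.thresholds(), inputs=inputs)
    return results
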