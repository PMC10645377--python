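"""Clinical-cohort biomarker stratification funnel.

Mirrors the stratification applied to a metastatic CRPC clinical
genomics cohort: merge polyA and capture RNA-seq sample lists to unique
samples, keep samples with at least 30% tumor content, then partition
sequentially — RB1 homozygous alteration; SLFN11 expression among
RB1-intact samples; ATR/CHD1 loss among the RB1-wt/SLFN11-negative
remainder; TP53 status among the rest. Samples positive at any of the
first three gates are considered biomarker-eligible for a
replication-stress-directed ADC, pending target-protein confirmation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import GenotypeState, _LOF_STATES, _WT_STATES
from .expression import Slfn11Method, call_slfn11

GENOTYPE_COLUMNS = ("RB1_state", "TP53_state", "ATR_state", "CHD1_state")


@dataclass(frozen=True)
class FunnelStage:
    name: str
    n_in: int
    n_positive: int  # branch meeting the stage condition

    @property
    def n_out(self) -> int:
        """Samples continuing to the next stage (condition-negative)."""
        return self.n_in - self.n_positive

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_in if self.n_in else 0.0


@dataclass(frozen=True)
class FunnelReport:
    stages: tuple[FunnelStage, ...]
    n_total: int
    n_filtered: int
    eligible: int

    @property
    def eligible_fraction(self) -> float:
        return self.eligible / self.n_filtered if self.n_filtered else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s.name, "n_in": s.n_in, "n_positive": s.n_positive,
              "n_out": s.n_out, "fraction": s.fraction} for s in self.stages])

    def to_text(self) -> str:
        lines = [f"cohort: {self.n_total} samples, "
                 f"{self.n_filtered} pass tumor-content filter"]
        for s in self.stages:
            lines.append(f"  {s.name}: {s.n_positive}/{s.n_in} "
                         f"({100 * s.fraction:.1f}%)")
        lines.append(f"eligible: {self.eligible}/{self.n_filtered} "
                     f"({100 * self.eligible_fraction:.1f}%)")
        return "\n".join(lines)


def merge_unique(polya: pd.DataFrame, capture: pd.DataFrame,
                 priority: str = "polya") -> pd.DataFrame:
    """Union of two assay tables keyed on sample_id, one row per sample.

    Where both assays cover a sample the priority table's row is kept
    (polyA first by default); a tumor-content disagreement above 0.05
    triggers a warning but the priority value is retained.
    """
    first, second = (polya, capture) if priority == "polya" else (capture, polya)
    overlap = first.merge(second, on="sample_id", suffixes=("_1", "_2"))
    if "tumor_content_1" in overlap.columns:
        bad = overlap[
            (overlap["tumor_content_1"] - overlap["tumor_content_2"]).abs() > 0.05]
        if len(bad):
            warnings.warn(
                f"tumor_content differs by > 0.05 for samples "
                f"{bad['sample_id'].tolist()}; keeping {priority} values",
                stacklevel=2)
    extra = second[~second["sample_id"].isin(first["sample_id"])]
    merged = pd.concat([first, extra], ignore_index=True)
    return merged.reset_index(drop=True)


def filter_tumor_content(cohort: pd.DataFrame,
                         min_fraction: float = 0.30) -> pd.DataFrame:
    """Keep samples with tumor_content >= min_fraction (inclusive)."""
    tc = cohort["tumor_content"]
    missing = tc.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} samples lack tumor_content; "
                      "dropped", stacklevel=2)
    return cohort[tc >= min_fraction].reset_index(drop=True)


def _state(series: pd.Series) -> pd.Series:
    return series.map(lambda s: GenotypeState(s))


def run_funnel(
    cohort: pd.DataFrame,
    slfn11_caller=None,
    min_tumor_content: float | None = None,
) -> FunnelReport:
    """Sequential biomarker partitioning of a (filtered) cohort table.

    ``slfn11_caller`` maps the SLFN11_expr vector of the RB1-intact
    subset to a boolean array; by default the package's mixture caller
    (falling back to a median split below the mixture's minimum cohort
    size). Eligible = RB1-altered ∪ SLFN11+ ∪ ATR/CHD1-loss.
    """
    n_total = len(cohort)
    if min_tumor_content is not None:
        cohort = filter_tumor_content(cohort, min_tumor_content)
    n_filtered = len(cohort)
    if n_filtered == 0:
        return FunnelReport(stages=(), n_total=n_total, n_filtered=0, eligible=0)

    rb1_lost = _state(cohort["RB1_state"]) == GenotypeState.BIALLELIC_LOSS
    stage1 = FunnelStage("RB1 homozygous alteration", n_filtered,
                         int(rb1_lost.sum()))

    intact = cohort[~rb1_lost]
    if slfn11_caller is None:
        def slfn11_caller(expr: np.ndarray) -> np.ndarray:
            if expr.size >= 20 and np.ptp(expr) > 0:
                return call_slfn11(expr, Slfn11Method.MIXTURE).status
            return expr > np.median(expr)
    if len(intact):
        slfn11_pos = np.asarray(
            slfn11_caller(intact["SLFN11_expr"].to_numpy(dtype=float)),
            dtype=bool)
    else:
        slfn11_pos = np.zeros(0, dtype=bool)
    stage2 = FunnelStage("SLFN11 expression (RB1 intact)", len(intact),
                         int(slfn11_pos.sum()))

    remainder = intact[~slfn11_pos]
    repair_loss = (
        _state(remainder["ATR_state"]).isin(_LOF_STATES)
        | _state(remainder["CHD1_state"]).isin(_LOF_STATES))
    stage3 = FunnelStage("ATR/CHD1 loss (RB1 wt, SLFN11 neg)", len(remainder),
                         int(repair_loss.sum()))

    rest = remainder[~repair_loss]
    tp53_wt = _state(rest["TP53_state"]).isin(_WT_STATES)
    stage4 = FunnelStage("TP53 wild type (no other biomarker)", len(rest),
                         int(tp53_wt.sum()))

    eligible = stage1.n_positive + stage2.n_positive + stage3.n_positive
    return FunnelReport(stages=(stage1, stage2, stage3, stage4),
                        n_total=n_total, n_filtered=n_filtered,
                        eligible=eligible)
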