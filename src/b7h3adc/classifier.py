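"""Composite biomarker decision rules for B7H3-PBD-ADC response.

A model (or, prospectively, a patient tumor) is mapped to a predicted
response class by an ordered rule list reflecting the identified
sensitivity pathways: target expression is a gate; RB1 loss or high
replication stress predicts response; SLFN11 expression predicts
response in RB1-intact adenocarcinoma; select DNA-repair lesions (ATR,
CHD1) rescue SLFN11-negative cases; an intact TP53 predicts
nonresponse. BRCA2 loss is carried but deliberately inert: the one
BRCA2-deficient, TP53-wild-type model observed was nonresponsive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd


class GenotypeState(str, Enum):
    BIALLELIC_LOSS = "biallelic_loss"
    ALTERED = "altered"
    MONOALLELIC_OR_WT = "monoallelic_or_wt"
    WT = "wt"


#: states counted as loss-of-function for the DNA-repair rule
_LOF_STATES = {GenotypeState.BIALLELIC_LOSS, GenotypeState.ALTERED}
#: states counted as an intact (wild-type-like) allele for the TP53 rule
_WT_STATES = {GenotypeState.WT, GenotypeState.MONOALLELIC_OR_WT}


class Prediction(str, Enum):
    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"
    INELIGIBLE = "ineligible"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ModelAnnotation:
    model_id: str
    phenotype: str
    b7h3_positive: bool
    genotypes: dict[str, GenotypeState]
    slfn11: bool
    b7h3_level: float = 0.0
    repstress_z: float | None = None
    rb1_score_z: float | None = None
    observed_response: str = "NA"  # R / NR / NA

    def __post_init__(self) -> None:
        missing = {"RB1", "TP53"} - set(self.genotypes)
        if missing:
            raise ValueError(
                f"{self.model_id}: missing genotypes {sorted(missing)}")


@dataclass(frozen=True)
class BiomarkerCall:
    model_id: str
    predicted: Prediction
    rule_fired: str
    rationale: str


@dataclass(frozen=True)
class ClassifierConfig:
    repstress_z_threshold: float = 1.0


def classify_model(annotation: ModelAnnotation,
                   config: ClassifierConfig = ClassifierConfig()) -> BiomarkerCall:
    """Apply the ordered decision rules; exactly one rule fires.

    Rule order: (1) target gate; (2) RB1 biallelic loss or replication
    stress above threshold; (3) SLFN11 expression; (4) ATR/CHD1
    loss-of-function; (5) intact TP53 → nonresponder; (6) indeterminate.
    """
    g = annotation.genotypes
    mid = annotation.model_id

    if not annotation.b7h3_positive:
        return BiomarkerCall(mid, Prediction.INELIGIBLE, "rule1_b7h3_gate",
                             "B7H3 not expressed: target antigen required")
    high_repstress = (annotation.repstress_z is not None
                      and annotation.repstress_z > config.repstress_z_threshold)
    if g["RB1"] == GenotypeState.BIALLELIC_LOSS or high_repstress:
        trigger = ("RB1 biallelic loss"
                   if g["RB1"] == GenotypeState.BIALLELIC_LOSS
                   else "replication stress score above threshold")
        return BiomarkerCall(mid, Prediction.RESPONDER, "rule2_rb1_repstress",
                             trigger)
    if annotation.slfn11:
        return BiomarkerCall(mid, Prediction.RESPONDER, "rule3_slfn11",
                             "SLFN11 expressed")
    if any(g.get(gene) in _LOF_STATES for gene in ("ATR", "CHD1")):
        gene = next(gg for gg in ("ATR", "CHD1") if g.get(gg) in _LOF_STATES)
        return BiomarkerCall(mid, Prediction.RESPONDER, "rule4_dna_repair",
                             f"{gene} loss of function")
    if g["TP53"] in _WT_STATES:
        return BiomarkerCall(mid, Prediction.NONRESPONDER, "rule5_tp53_wt",
                             "TP53 wild type")
    return BiomarkerCall(mid, Prediction.INDETERMINATE, "rule6_default",
                         "TP53 altered but no positive biomarker")


def classify_models(annotations: list[ModelAnnotation],
                    config: ClassifierConfig = ClassifierConfig()
                    ) -> list[BiomarkerCall]:
    return [classify_model(a, config) for a in annotations]


def evaluate_calls(calls: list[BiomarkerCall],
                   annotations: list[ModelAnnotation]) -> dict:
    """Confusion summary over eligible labelled models plus named tallies.

    The named counts mirror the study's printed biomarker bookkeeping
    and are computed directly from the annotation columns:
    SLFN11+ ARPC responders, SLFN11− ARPC responders and the SLFN11−
    ARPC denominator, TP53-wt SLFN11− ARPC nonresponders, RB1-deficient
    models that are SLFN11+, and total ARPC nonresponders.
    """
    ids = [a.model_id for a in annotations]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated model_id: {dup}")
    call_by_id = {c.model_id: c for c in calls}
    if len(call_by_id) != len(calls):
        raise ValueError("duplicated model_id in calls")

    confusion = {(p, o): 0 for p in ("responder", "nonresponder")
                 for o in ("R", "NR")}
    for a in annotations:
        c = call_by_id.get(a.model_id)
        if c is None or a.observed_response == "NA":
            continue
        if c.predicted in (Prediction.RESPONDER, Prediction.NONRESPONDER):
            confusion[(c.predicted.value, a.observed_response)] += 1

    def _count(pred):
        return sum(1 for a in annotations if pred(a))

    arpc = lambda a: a.phenotype == "ARPC"
    rb1_def = lambda a: a.genotypes["RB1"] == GenotypeState.BIALLELIC_LOSS
    counts = {
        "slfn11_pos_arpc": _count(lambda a: arpc(a) and a.slfn11),
        "slfn11_pos_arpc_responders": _count(
            lambda a: arpc(a) and a.slfn11 and a.observed_response == "R"),
        "slfn11_neg_arpc": _count(lambda a: arpc(a) and not a.slfn11),
        "slfn11_neg_arpc_responders": _count(
            lambda a: arpc(a) and not a.slfn11 and a.observed_response == "R"),
        "slfn11_neg_arpc_nonresponders": _count(
            lambda a: arpc(a) and not a.slfn11 and a.observed_response == "NR"),
        "slfn11_neg_nonresponders_tp53_wt": _count(
            lambda a: arpc(a) and not a.slfn11 and a.observed_response == "NR"
            and a.genotypes["TP53"] in _WT_STATES),
        "rb1_deficient": _count(rb1_def),
        "rb1_deficient_slfn11_pos": _count(lambda a: rb1_def(a) and a.slfn11),
        "arpc_nonresponders": _count(
            lambda a: arpc(a) and a.observed_response == "NR"),
    }
    return {"confusion": confusion, "counts": counts}
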