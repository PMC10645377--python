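"""IHC H-score quantification for tissue-microarray cores.

H-score = Σ_i (percent cells at intensity i × i) for i in 1..3, giving a
composite in [0, 300]. Triplicate core scores are averaged per tumor and
a tumor is called a B7H3 expressor when its averaged H-score exceeds 20
(strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SUM_TOLERANCE = 0.5  # absorbs rounded percentage tables


@dataclass(frozen=True)
class IHCCore:
    tumor_id: str
    core_id: str
    pct_at_intensity: tuple[float, float, float, float]  # intensities 0..3
    evaluable: bool = True

    def __post_init__(self) -> None:
        pct = tuple(float(p) for p in self.pct_at_intensity)
        object.__setattr__(self, "pct_at_intensity", pct)
        if len(pct) != 4:
            raise ValueError("pct_at_intensity must have 4 entries (0-3)")
        if self.evaluable:
            if any(p < 0 for p in pct):
                raise ValueError("percentages must be nonnegative")
            if abs(sum(pct) - 100.0) > SUM_TOLERANCE:
                raise ValueError(
                    f"core {self.tumor_id}/{self.core_id}: percentages sum to "
                    f"{sum(pct):g}, not 100")


def compute_hscore(core: IHCCore) -> float:
    """Weighted-intensity score: Σ pct_i × i over intensities 1..3."""
    if not core.evaluable:
        raise ValueError(f"core {core.tumor_id}/{core.core_id} is not evaluable")
    return float(sum(p * i for i, p in enumerate(core.pct_at_intensity)))


def average_cores(cores: list[IHCCore]) -> float | None:
    """Mean H-score over the evaluable cores of one tumor.

    Returns None (tumor not analyzed) when no core is evaluable, as for
    cores with insufficient tumor content.
    """
    scores = [compute_hscore(c) for c in cores if c.evaluable]
    if not scores:
        return None
    return float(np.mean(scores))


def classify_expressor(h: float, cutoff: float = 20.0) -> bool:
    """Expressor iff averaged H-score is strictly above the cutoff."""
    if not 0 <= h <= 300:
        raise ValueError(f"H-score {h} outside [0, 300]")
    return h > cutoff


def summarize_tma(
    cores: list[IHCCore],
    phenotypes: dict[str, str] | None = None,
    cutoff: float = 20.0,
) -> dict:
    """Tumor-level TMA summary: evaluable / expressor / non-expressor counts.

    ``expressors + non_expressors == evaluable`` and
    ``evaluable + not_analyzed == total``; optional per-phenotype
    expressor counts when a tumor→phenotype annotation is given.
    """
    by_tumor: dict[str, list[IHCCore]] = {}
    for c in cores:
        by_tumor.setdefault(c.tumor_id, []).append(c)

    records = []
    for tumor_id, tumor_cores in by_tumor.items():
        h = average_cores(tumor_cores)
        records.append({
            "tumor_id": tumor_id,
            "h_score": h,
            "analyzed": h is not None,
            "expressor": classify_expressor(h, cutoff) if h is not None else None,
            "phenotype": (phenotypes or {}).get(tumor_id),
        })
    table = pd.DataFrame(records)
    evaluable = int(table["analyzed"].sum())
    expressors = int(table["expressor"].eq(True).sum())
    summary = {
        "total": len(table),
        "evaluable": evaluable,
        "not_analyzed": len(table) - evaluable,
        "expressors": expressors,
        "non_expressors": evaluable - expressors,
        "cutoff": cutoff,
        "table": table,
    }
    if phenotypes is not None:
        grp = (table[table["analyzed"]]
               .groupby("phenotype", dropna=False)["expressor"]
               .agg(["count", "sum"]))
        summary["by_phenotype"] = {
            str(k): {"evaluable": int(v["count"]), "expressors": int(v["sum"])}
            for k, v in grp.iterrows()}
    return summary
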