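"""Readers and writers for every interchange format the pipeline uses.

Tables are UTF-8, tab- or comma-delimited by extension, decimal point
only. All writers go through an atomic temp-then-rename step so no
partial output survives a failure, and every pipeline run emits a
provenance JSON with versions, seeds, thresholds and input digests.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import Agent, DoseResponseExperiment
from .expression import ExpressionMatrix, Scale
from .histology import IHCCore
from .signatures import GeneSet, SignatureScores


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to path via a temp file in the same directory + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line, tab-separated name, description, members."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (< 3 fields)")
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets.append(GeneSet.from_list(name, genes, description))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *sorted(s.genes)])
             for s in sets]
    atomic_write_text(path, "\n".join(lines) + "\n")


# --------------------------------------------------------------- expression

def read_expression(path: str | Path, scale: Scale | str) -> ExpressionMatrix:
    """Gene-by-sample table; genes as rows. Non-numeric cells are named."""
    sep = _sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"{path}: non-numeric value at gene {gene!r}, sample {sample!r}")
    if numeric.isna().any().any():
        raise ValueError(f"{path}: missing values in expression table")
    return ExpressionMatrix(values=numeric, scale=Scale(scale))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    atomic_write_text(path, matrix.values.to_csv(sep=_sep(path)))


# ------------------------------------------------------------ dose response

DOSE_COLUMNS = ["model", "agent", "experiment", "dose", "unit",
                "replicate", "viability"]
_UNIT_TO_UGML = {"ug/mL": 1.0, "μg/mL": 1.0, "ng/mL": 1e-3}


def read_dose_response(path: str | Path) -> dict[str, list[DoseResponseExperiment]]:
    """Long-format curves CSV → experiments grouped by model.

    Doses are converted to μg/mL; accepted units: ng/mL, μg/mL (ug/mL).
    """
    table = pd.read_csv(path, sep=_sep(path))
    missing = set(DOSE_COLUMNS) - {"unit"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "unit" in table.columns:
        factor = table["unit"].map(_UNIT_TO_UGML)
        if factor.isna().any():
            bad = sorted(table.loc[factor.isna(), "unit"].unique())
            raise ValueError(f"{path}: unknown dose units {bad}")
        table = table.assign(dose=table["dose"] * factor)
    out: dict[str, list[DoseResponseExperiment]] = {}
    for (model, agent, exp_id), grp in table.groupby(
            ["model", "agent", "experiment"], sort=True):
        pivot = grp.pivot_table(index="dose", columns="replicate",
                                values="viability")
        out.setdefault(str(model), []).append(DoseResponseExperiment(
            model_id=str(model), agent=Agent(agent),
            doses=pivot.index.to_numpy(dtype=float),
            viability=pivot.to_numpy(dtype=float),
            experiment_id=str(exp_id)))
    return out


def write_dose_response(experiments: list[DoseResponseExperiment],
                        path: str | Path) -> None:
    rows = []
    for e in experiments:
        for i, dose in enumerate(e.doses):
            for r in range(e.viability.shape[1]):
                rows.append((e.model_id, e.agent.value, e.experiment_id,
                             dose, "ug/mL", r + 1, e.viability[i, r]))
    table = pd.DataFrame(rows, columns=DOSE_COLUMNS)
    atomic_write_text(path, table.to_csv(index=False, sep=_sep(path)))


# ---------------------------------------------------------------------- IHC

IHC_COLUMNS = ["tumor_id", "core_id", "pct0", "pct1", "pct2", "pct3",
               "evaluable"]


def read_ihc(path: str | Path) -> list[IHCCore]:
    table = pd.read_csv(path, sep=_sep(path))
    missing = set(IHC_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        IHCCore(tumor_id=str(r.tumor_id), core_id=str(r.core_id),
                pct_at_intensity=(r.pct0, r.pct1, r.pct2, r.pct3),
                evaluable=bool(r.evaluable))
        for r in table.itertuples()
    ]


def write_ihc(cores: list[IHCCore], path: str | Path) -> None:
    table = pd.DataFrame(
        [(c.tumor_id, c.core_id, *c.pct_at_intensity, c.evaluable)
         for c in cores], columns=IHC_COLUMNS)
    atomic_write_text(path, table.to_csv(index=False, sep=_sep(path)))


# ------------------------------------------------------------------- cohort

def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=_sep(path))
    required = {"sample_id", "tumor_content", "RB1_state", "TP53_state",
                "ATR_state", "CHD1_state", "SLFN11_expr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, cohort.to_csv(index=False, sep=_sep(path)))


# ------------------------------------------------------------------- scores

def write_scores(scores: SignatureScores, path: str | Path) -> None:
    """Scores TSV: one row per (signature, sample) with raw and z columns."""
    raw = scores.raw_scores.stack().rename("raw_score")
    out = raw.reset_index()
    out.columns = ["signature", "sample", "raw_score"]
    if scores.z_scores is not None:
        z = scores.z_scores.stack().rename("z_score").reset_index()
        z.columns = ["signature", "sample", "z_score"]
        out = out.merge(z, on=["signature", "sample"])
    atomic_write_text(path, out.to_csv(index=False, sep=_sep(path)))


def read_scores(path: str | Path) -> SignatureScores:
    table = pd.read_csv(path, sep=_sep(path))
    raw = table.pivot(index="signature", columns="sample", values="raw_score")
    z = None
    if "z_score" in table.columns:
        z = table.pivot(index="signature", columns="sample", values="z_score")
    raw.index.name = None
    raw.columns.name = None
    if z is not None:
        z.index.name = None
        z.columns.name = None
    return SignatureScores(raw_scores=raw, z_scores=z)


# --------------------------------------------------------------- provenance

def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path: str | Path, *, seed: int | None,
                     thresholds: dict, inputs: list[str | Path]) -> None:
    record = {
        "package": "b7h3adc",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "thresholds": thresholds,
        "input_digests": {str(p): file_digest(p) for p in inputs
                          if Path(p).exists()},
    }
    atomic_write_text(path, json.dumps(record, indent=2, sort_keys=True) + "\n")
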