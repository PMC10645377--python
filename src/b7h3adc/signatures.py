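"""Single-sample gene-set scoring and the signature-vs-response screen.

Each sample is scored for a gene set by the ssGSEA running sum: genes
are ranked by expression within the sample and the enrichment score is
the summed difference between the rank-weighted in-set empirical CDF
(weights |rank|^alpha, alpha = 0.25 by default) and the unweighted
out-of-set CDF, walked from the highest-expressed gene down. Raw scores
are rescaled by the cohort score range so that scores are comparable
across signatures, then z-transformed for phenotype calling (AR/NE
quadrants) and for the univariate Spearman screen against nAUC with
Benjamini-Hochberg control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_list(cls, name: str, genes: list[str],
                  description: str = "") -> "GeneSet":
        seen = set()
        for g in genes:
            if g in seen:
                warnings.warn(f"duplicate gene {g!r} in set {name!r}; "
                              "de-duplicated", stacklevel=2)
            seen.add(g)
        return cls(name=name, genes=frozenset(seen), description=description)


@dataclass
class SignatureScores:
    raw_scores: pd.DataFrame  # signatures as rows, samples as columns
    z_scores: pd.DataFrame | None = None

    @property
    def samples(self) -> pd.Index:
        return self.raw_scores.columns

    @property
    def signatures(self) -> pd.Index:
        return self.raw_scores.index


def _sample_enrichment(expr: np.ndarray, in_set: np.ndarray,
                       alpha: float) -> float:
    """Running-sum enrichment of one sample (expr: per-gene values)."""
    ranks = stats.rankdata(expr, method="average")
    order = np.argsort(-ranks, kind="stable")  # highest expression first
    r_sorted = ranks[order]
    in_sorted = in_set[order]
    w = np.abs(r_sorted) ** alpha
    w_in = np.where(in_sorted, w, 0.0)
    denom_in = w_in.sum()
    n_out = np.count_nonzero(~in_set)
    cdf_in = np.cumsum(w_in) / denom_in
    cdf_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample ssGSEA enrichment score for one gene set.

    With ``normalize=True`` raw running sums are divided by the score
    range (max − min) across the cohort, the cited method's default.
    Raises if fewer than 2 set genes are present in the matrix or the
    set covers every gene (no complement to integrate against).
    """
    genes_present = matrix.genes.intersection(gene_set.genes)
    if len(genes_present) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r}: fewer than 2 member genes present")
    if len(genes_present) == len(matrix.genes):
        raise ValueError(
            f"gene set {gene_set.name!r} covers all genes; no complement")
    in_set = np.asarray(matrix.genes.isin(gene_set.genes))
    vals = matrix.values.to_numpy()
    scores = np.array([
        _sample_enrichment(vals[:, j], in_set, alpha)
        for j in range(vals.shape[1])
    ])
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return pd.Series(scores, index=matrix.samples, name=gene_set.name)


def score_signatures(
    matrix: ExpressionMatrix,
    gene_sets: list[GeneSet],
    alpha: float = 0.25,
    normalize: bool = True,
) -> SignatureScores:
    """Score several gene sets; normalization uses the global score range."""
    raw = pd.DataFrame(
        {gs.name: ssgsea_score(matrix, gs, alpha=alpha, normalize=False)
         for gs in gene_sets}).T
    if normalize:
        rng = raw.to_numpy().max() - raw.to_numpy().min()
        if rng > 0:
            raw = raw / rng
    return SignatureScores(raw_scores=raw)


def z_transform(scores: SignatureScores) -> SignatureScores:
    """Per-signature z-scores across the cohort (sample sd, ddof=1)."""
    raw = scores.raw_scores
    if raw.shape[1] < 2:
        raise ValueError("z-transform requires at least 2 samples")
    sd = raw.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance signatures: {flat.index.tolist()}")
    z = raw.sub(raw.mean(axis=1), axis=0).div(sd, axis=0)
    return SignatureScores(raw_scores=raw, z_scores=z)


PHENOTYPES = ("ARPC", "DNPC", "SCNPC", "amphicrine")


def call_phenotype(ar_score: float, ne_score: float,
                   ar_cutoff: float = 0.0, ne_cutoff: float = 0.0) -> str:
    """Quadrant phenotype from AR and neuroendocrine z-scores.

    AR+/NE− adenocarcinoma (ARPC); AR−/NE− double-negative (DNPC);
    AR−/NE+ small-cell neuroendocrine (SCNPC); AR+/NE+ amphicrine.
    """
    ar_pos = ar_score > ar_cutoff
    ne_pos = ne_score > ne_cutoff
    if ar_pos and not ne_pos:
        return "ARPC"
    if not ar_pos and not ne_pos:
        return "DNPC"
    if not ar_pos and ne_pos:
        return "SCNPC"
    return "amphicrine"


def correlate_with_response(
    nauc: pd.Series,
    scores: SignatureScores,
    method: str = "spearman",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Univariate screen: each signature's z-score vs per-model nAUC.

    Returns one row per signature with coefficient, two-sided p and
    BH-adjusted FDR, sorted by |coefficient| among FDR-significant hits
    first. Constant score vectors are reported with NaN coefficients and
    excluded from the FDR adjustment.
    """
    if scores.z_scores is None:
        # tolerate constant signatures here: they are reported with NaN
        # coefficients rather than failing the whole screen
        raw = scores.raw_scores
        sd = raw.std(axis=1, ddof=1)
        z = raw.sub(raw.mean(axis=1), axis=0).div(sd.replace(0, np.nan),
                                                  axis=0)
        scores = SignatureScores(raw_scores=raw, z_scores=z)
    shared = scores.samples.intersection(nauc.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 models shared between scores and nAUC")
    y = nauc.loc[shared].to_numpy(dtype=float)
    corr_fn = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]

    rows = []
    for sig in scores.signatures:
        x = scores.z_scores.loc[sig, shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((sig, np.nan, np.nan))
            continue
        res = corr_fn(x, y)
        rows.append((sig, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["signature", "coefficient", "p"])
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] <= fdr_threshold
    out = out.sort_values(
        by=["significant", "coefficient"],
        key=lambda s: s.abs() if s.name == "coefficient" else s,
        ascending=[False, False],
    ).reset_index(drop=True)
    return out


def group_compare(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Holm adjustment.

    Groups with fewer than 2 members are dropped with a warning. Exact
    p-values are used where SciPy supports them (no ties, small n).
    """
    values, groups = values.align(groups, join="inner")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(f"excluding groups with < 2 values: "
                      f"{small.index.tolist()}", stacklevel=2)
    labels = sorted(sizes[sizes >= 2].index)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        xa = values[groups == a].to_numpy(dtype=float)
        xb = values[groups == b].to_numpy(dtype=float)
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p"])
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
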