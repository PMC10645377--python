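"""Expression normalization and SLFN11 expressor calling.

Bulk RNA-seq counts are normalized between samples with the trimmed mean
of M-values (TMM) and converted to log2 counts-per-million; an
ordered-quantile (rank inverse-normal) transform is provided for
putting clinical expression vectors on a normal scale; and SLFN11
expressor status is called from a cohort's log-scale expression with a
two-component Gaussian mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture


class Scale(str, Enum):
    RAW_COUNTS = "raw_counts"
    LOG2_CPM = "log2_cpm"
    LOG2_FPKM = "log2_fpkm"
    QUANTILE_NORMAL = "quantile_normal"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample table with an explicit normalization state."""

    values: pd.DataFrame  # genes as rows, samples as columns
    scale: Scale

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene identifiers: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample identifiers: {dups}")
        if self.scale == Scale.RAW_COUNTS and (self.values.values < 0).any():
            raise ValueError("raw counts must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def library_sizes(self) -> pd.Series:
        if self.scale != Scale.RAW_COUNTS:
            raise ValueError("library sizes are defined for raw counts only")
        return self.values.sum(axis=0)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.30,
                     abs_trim: float = 0.05) -> float:
    """TMM scaling factor of one library against the reference.

    Genes with a zero in either library are excluded; the top/bottom 30%
    by M (log-ratio) and 5% by A (log-abundance) are trimmed; the factor
    is the weighted mean of surviving M-values with inverse
    asymptotic-variance (delta-method binomial) weights, exponentiated.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    if np.max(np.abs(m)) < 1e-6:  # identical relative composition
        return 1.0

    n = m.size
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * abs_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_normalize(counts: ExpressionMatrix) -> tuple[pd.Series, ExpressionMatrix]:
    """TMM between-sample normalization followed by log2 CPM conversion.

    The reference sample is the one whose upper-quartile count fraction
    is closest to the mean upper quartile. Scaling factors are
    renormalized to geometric mean 1 and applied through effective
    library sizes; log2 CPM uses a 0.5 pseudo-count.
    """
    if counts.scale != Scale.RAW_COUNTS:
        raise ValueError("tmm_normalize requires raw counts")
    mat = counts.values
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = mat.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"samples with zero total count: {zero.index.tolist()}")

    uq = (mat / lib).quantile(0.75, axis=0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = mat[ref_sample].to_numpy()
    lib_ref = float(lib[ref_sample])

    factors = pd.Series(
        {s: _tmm_pair_factor(mat[s].to_numpy(), ref, float(lib[s]), lib_ref)
         for s in mat.columns},
        name="tmm_factor")
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1

    eff_lib = lib * factors
    log_cpm = np.log2((mat + 0.5) / eff_lib * 1e6)
    return factors, ExpressionMatrix(values=log_cpm, scale=Scale.LOG2_CPM)


def ordered_quantile_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform Φ⁻¹((rank − 0.5)/n).

    Ties receive average ranks; any strictly monotone transform of the
    input yields the identical output.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.ptp(arr) == 0:
        raise ValueError("all values identical: no ordering information")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


class Slfn11Method(str, Enum):
    MIXTURE = "mixture"
    THRESHOLD = "threshold"


@dataclass(frozen=True)
class Slfn11Call:
    status: np.ndarray  # boolean per sample
    positive_fraction: float
    method: Slfn11Method
    params: dict
    fallback: bool = False


def call_slfn11(
    expression: np.ndarray | pd.Series,
    method: Slfn11Method = Slfn11Method.MIXTURE,
    threshold: float = 0.0,
    random_state: int = 0,
) -> Slfn11Call:
    """Binary SLFN11 expressor status across a cohort.

    The mixture method fits a 2-component Gaussian mixture on the
    supplied values (expected on a log/variance-stabilized scale) and
    assigns positives to the higher-mean component at posterior > 0.5.
    The fit is treated as degenerate — and falls back, with a warning,
    to a single cohort-wide status (whether the overall mean exceeds
    the threshold) — when a component collapses (weight < 0.02) or the
    component means are separated by less than 2 pooled standard
    deviations, i.e. the cohort is effectively unimodal. This is the
    package's own operational rule, not a published cutoff; its
    parameters are recorded in the returned call.
    """
    arr = np.asarray(expression, dtype=float)
    if method == Slfn11Method.THRESHOLD:
        status = arr > threshold
        return Slfn11Call(status=status,
                          positive_fraction=float(status.mean()),
                          method=method, params={"threshold": threshold})

    if arr.size < 20:
        raise ValueError("mixture method requires cohort size >= 20")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    gm.fit(arr.reshape(-1, 1))
    means = gm.means_.ravel()
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    separation = abs(means[1] - means[0]) / pooled_sd
    if gm.weights_.min() < 0.02 or separation < 2.0:
        warnings.warn("degenerate mixture fit (unimodal cohort); assigning "
                      "a single cohort-wide status", stacklevel=2)
        one_status = bool(arr.mean() > threshold)
        status = np.full(arr.size, one_status)
        return Slfn11Call(status=status,
                          positive_fraction=float(status.mean()),
                          method=Slfn11Method.THRESHOLD,
                          params={"threshold": threshold,
                                  "separation": separation}, fallback=True)
    hi = int(np.argmax(means))
    post = gm.predict_proba(arr.reshape(-1, 1))[:, hi]
    status = post > 0.5
    return Slfn11Call(
        status=status,
        positive_fraction=float(status.mean()),
        method=method,
        params={
            "means": means.tolist(),
            "weights": gm.weights_.tolist(),
            "sds": np.sqrt(gm.covariances_.ravel()).tolist(),
        },
    )
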