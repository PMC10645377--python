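"""Dose–response summaries for paired targeted/control ADC viability curves.

The central statistic is the normalized AUC (nAUC): the ratio of the
area under the targeted-ADC viability curve to the area under the
isotype-control curve, both taken over log10(dose) and normalized by the
log-dose span so that a curve pinned at 100% viability integrates to
exactly 1. nAUC < 1 therefore measures target-specific killing; the
median nAUC over independent experiments is the per-model response
statistic, and responder status is called by a strict threshold on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import curve_fit


class Agent(str, Enum):
    TARGETED = "targeted"
    CONTROL = "control"


class ResponderCall(str, Enum):
    R = "R"
    NR = "NR"


@dataclass(frozen=True)
class DoseResponseExperiment:
    """One viability titration of one model with one agent.

    doses are in μg/mL, strictly increasing, at least 4 levels;
    viability is a (n_doses, n_replicates) array of percent-of-control
    values, nonnegative and allowed to exceed 100.
    """

    model_id: str
    agent: Agent
    doses: np.ndarray
    viability: np.ndarray
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if viab.shape[0] != doses.size:
            viab = viab.T
        if viab.shape[0] != doses.size:
            raise ValueError(
                f"viability shape {viab.shape} does not match {doses.size} doses"
            )
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", viab)
        if doses.size < 4:
            raise ValueError(f"need >= 4 dose levels, got {doses.size}")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(~np.isfinite(viab)) or np.any(viab < 0):
            raise ValueError("viability must be finite and nonnegative")

    @property
    def mean_viability(self) -> np.ndarray:
        """Replicates averaged per dose (the curve that is integrated)."""
        return self.viability.mean(axis=1)


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of mean viability vs log10(dose)."""

    top: float
    bottom: float
    ic50: float
    slope: float
    converged: bool
    rss: float
    ic50_in_range: bool = True

    def __post_init__(self) -> None:
        if self.converged and not self.ic50 > 0:
            raise ValueError("converged fit requires ic50 > 0")
        if self.converged and self.bottom > self.top:
            raise ValueError("bottom must not exceed top")


@dataclass(frozen=True)
class DoseResponseSummary:
    model_id: str
    nauc_median: float
    nauc_iqr: float
    per_experiment_nauc: tuple[float, ...]
    ic50: float | None
    maxr: float
    responder: ResponderCall | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.per_experiment_nauc:
            raise ValueError("per_experiment_nauc must be nonempty")
        if not self.nauc_median > 0:
            raise ValueError("nauc_median must be positive")
        if self.maxr < 0:
            raise ValueError("maxr must be nonnegative")


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float,
            slope: float) -> np.ndarray:
    """Decreasing 4PL curve: viability(d) = bottom + (top-bottom)/(1+(d/ic50)^slope)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** slope)


def fit_4pl(experiment: DoseResponseExperiment) -> FourPLFit:
    """Least-squares 4PL fit on mean viability vs log10(dose).

    Never raises on a flat or pathological curve; instead returns
    ``converged=False``. A numeric IC50 is only trusted (``ic50_in_range``)
    when the fitted midpoint lies inside the tested dose range.
    """
    doses = experiment.doses
    y = experiment.mean_viability
    log_d = np.log10(doses)

    y_range = y.max() - y.min()
    if y_range < 1e-9:
        return FourPLFit(top=float(y[0]), bottom=float(y[0]), ic50=np.nan,
                         slope=np.nan, converged=False, rss=0.0,
                         ic50_in_range=False)

    def model(ld: np.ndarray, top: float, bottom: float, log_ic50: float,
              slope: float) -> np.ndarray:
        with np.errstate(over="ignore"):  # saturates to `bottom`, not an error
            return bottom + (top - bottom) / (
                1.0 + 10.0 ** (slope * (ld - log_ic50)))

    # midpoint guess: dose where the curve crosses halfway between extremes
    half = (y.max() + y.min()) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    p0 = (float(y.max()), float(y.min()), float(log_d[idx]), 1.0)
    try:
        popt, _ = curve_fit(
            model, log_d, y, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, log_d[0] - 6, 0.01],
                    [np.inf, np.inf, log_d[-1] + 6, 50.0]),
        )
    except (RuntimeError, ValueError):
        return FourPLFit(top=np.nan, bottom=np.nan, ic50=np.nan, slope=np.nan,
                         converged=False, rss=np.nan, ic50_in_range=False)
    top, bottom, log_ic50, slope = popt
    if bottom > top:  # reparametrize to the canonical orientation
        top, bottom = bottom, top
    rss = float(np.sum((model(log_d, *popt) - y) ** 2))
    in_range = bool(log_d[0] <= log_ic50 <= log_d[-1])
    return FourPLFit(top=float(top), bottom=float(bottom),
                     ic50=float(10.0 ** log_ic50), slope=float(slope),
                     converged=True, rss=rss, ic50_in_range=in_range)


def compute_auc(experiment: DoseResponseExperiment) -> float:
    """Normalized area under mean viability over log10(dose).

    Trapezoidal integral divided by (100 × log10-dose span): a curve at
    a constant 100% viability scores exactly 1.0, full kill scores 0.
    Invariant under rescaling all doses by a common factor.
    """
    doses = experiment.doses
    if doses.size < 2:
        raise ValueError("AUC requires at least 2 dose levels")
    log_d = np.log10(doses)
    span = log_d[-1] - log_d[0]
    y = experiment.mean_viability
    return float(np.trapezoid(y, log_d) / (100.0 * span))


def compute_nauc(
    targeted: list[DoseResponseExperiment],
    control: list[DoseResponseExperiment],
    responder_threshold: float | None = None,
) -> DoseResponseSummary:
    """Pair targeted/control experiments by experiment_id and summarize.

    Per pair, nAUC = AUC(targeted) / AUC(control). The per-model summary
    takes the median and interquartile range over pairs; IC50 and MaxR
    (viability at the top dose) come from the pooled targeted curves.
    """
    t_by_id = {e.experiment_id: e for e in targeted}
    c_by_id = {e.experiment_id: e for e in control}
    if len(t_by_id) != len(targeted) or len(c_by_id) != len(control):
        raise ValueError("duplicated experiment_id within an arm")
    unpaired = sorted(set(t_by_id) ^ set(c_by_id))
    if unpaired:
        raise ValueError(f"unpaired experiment_ids: {unpaired}")
    if not t_by_id:
        raise ValueError("need at least one experiment pair")

    naucs = []
    for eid in sorted(t_by_id):
        auc_c = compute_auc(c_by_id[eid])
        if auc_c == 0:
            raise ValueError(f"degenerate control curve (AUC=0) in {eid!r}")
        naucs.append(compute_auc(t_by_id[eid]) / auc_c)
    naucs_arr = np.array(naucs)
    q1, q3 = np.percentile(naucs_arr, [25, 75])

    # IC50 / MaxR from the targeted arm, replicate-averaged across experiments
    first = t_by_id[sorted(t_by_id)[0]]
    pooled_viab = np.hstack([t_by_id[eid].viability for eid in sorted(t_by_id)])
    pooled = DoseResponseExperiment(
        model_id=first.model_id, agent=Agent.TARGETED,
        doses=first.doses, viability=pooled_viab, experiment_id="pooled")
    fit = fit_4pl(pooled)
    ic50 = fit.ic50 if (fit.converged and fit.ic50_in_range) else None
    maxr = float(pooled.mean_viability[-1])

    summary = DoseResponseSummary(
        model_id=first.model_id,
        nauc_median=float(np.median(naucs_arr)),
        nauc_iqr=float(q3 - q1),
        per_experiment_nauc=tuple(naucs),
        ic50=ic50,
        maxr=maxr,
    )
    if responder_threshold is not None:
        call = call_responder(summary, responder_threshold)
        summary = DoseResponseSummary(
            **{**summary.__dict__, "responder": call,
               "threshold": responder_threshold})
    return summary


def call_responder(summary: DoseResponseSummary,
                   threshold: float = 0.75) -> ResponderCall:
    """R iff median nAUC is strictly below the threshold (ties are NR)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return ResponderCall.R if summary.nauc_median < threshold else ResponderCall.NR
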