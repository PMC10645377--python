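"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage (normalization, signature scoring, dose-response
summarization, SLFN11 calling, IHC scoring, the cohort funnel) can be
exercised without any download: this module generates

* negative-binomial RNA-seq count matrices with planted gene-set shifts
  (log2 effect δ in a configured fraction of samples),
* paired targeted/control viability titrations following per-model 4PL
  curves plus Gaussian noise truncated at 0 (values above 100 are kept:
  viability is relative to an untreated control and may exceed it),
* clinical cohort tables with configured genotype alteration
  frequencies, a Beta-distributed tumor content and a two-component
  SLFN11 expression mixture,
* triplicate-core IHC intensity-percentage tables.

One global seed is split into fixed named substreams so adding a
generator never perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import Agent, DoseResponseExperiment, four_pl


@dataclass(frozen=True)
class PlantedSet:
    name: str
    genes: tuple[str, ...]
    delta: float  # log2 shift in member-gene means
    affected_fraction: float


@dataclass(frozen=True)
class HillParams:
    top: float
    bottom: float
    ic50: float  # μg/mL
    slope: float


#: control-arm curve: essentially flat near 100% over the tested range
CONTROL_CURVE = HillParams(top=100.0, bottom=0.0, ic50=500.0, slope=1.0)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2000
    n_samples: int = 26
    nb_dispersion: float = 0.1
    planted_sets: tuple[PlantedSet, ...] = ()
    slfn11_mixture: tuple[float, float, float, float] = (2.0, 6.0, 1.0, 0.40)
    genotype_freqs: dict = field(default_factory=lambda: {
        "RB1": 0.10, "TP53": 0.40, "ATR": 0.02, "CHD1": 0.02})
    tumor_content_beta: tuple[float, float] = (3.0, 2.0)
    hill_params: dict = field(default_factory=dict)  # model_id -> HillParams
    dose_grid: tuple[float, ...] = tuple(4.0 * 4.0 ** -i for i in range(9, -1, -1))
    replicates: int = 5
    n_experiments: int = 3
    noise_sd: float = 5.0
    ihc_profiles: tuple[tuple[float, float, float, float], ...] = (
        (100.0, 0.0, 0.0, 0.0),
        (70.0, 20.0, 10.0, 0.0),
        (20.0, 30.0, 40.0, 10.0),
        (0.0, 10.0, 30.0, 60.0),
    )
    ihc_tumors_per_profile: int = 3
    ihc_concentration: float | None = None  # Dirichlet conc.; None = exact

    def __post_init__(self) -> None:
        for ps in self.planted_sets:
            if not 0 <= ps.affected_fraction <= 1:
                raise ValueError(f"{ps.name}: affected_fraction not in [0,1]")
        low, high, sd, frac = self.slfn11_mixture
        if not 0 <= frac <= 1:
            raise ValueError("SLFN11 positive fraction must be in [0,1]")
        if sd <= 0:
            raise ValueError("SLFN11 mixture sd must be positive")
        for gene, f in self.genotype_freqs.items():
            if not 0 <= f <= 1:
                raise ValueError(f"{gene}: alteration fraction not in [0,1]")
        doses = np.asarray(self.dose_grid)
        if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValueError("dose_grid must be positive, strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for p in self.ihc_profiles:
            if abs(sum(p) - 100.0) > 1e-6 or any(x < 0 for x in p):
                raise ValueError(f"IHC profile {p} must be nonnegative and "
                                 "sum to 100")


_STREAMS = {"expression": 0, "dose_response": 1, "cohort": 2, "ihc": 3}


def _rng(config: SimulationConfig, stream: str,
         substream: str | None = None) -> np.random.Generator:
    key = [_STREAMS[stream]]
    if substream is not None:
        key.append(zlib.crc32(substream.encode()))
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    return np.random.default_rng(ss)


def gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw count matrix (genes × samples) plus planted-label truth table.

    Per-gene log2 means are drawn N(5, 2); counts are negative binomial
    with a fixed dispersion (the standard bulk RNA-seq noise model).
    For each planted set, a configured fraction of samples has its
    member-gene means multiplied by 2**δ; the truth table records which
    samples carry which planted signal.
    """
    rng = _rng(config, "expression")
    genes = gene_names(config.n_genes)
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    known = set(genes)
    for ps in config.planted_sets:
        unknown = sorted(set(ps.genes) - known)
        if unknown:
            raise ValueError(
                f"planted set {ps.name!r} references unknown genes: {unknown}")

    log2_mu = rng.normal(5.0, 2.0, size=config.n_genes)
    mu = np.tile(2.0 ** log2_mu[:, None], (1, config.n_samples))

    truth = pd.DataFrame(False, index=samples,
                         columns=[ps.name for ps in config.planted_sets])
    gene_idx = {g: i for i, g in enumerate(genes)}
    for ps in config.planted_sets:
        n_affected = int(round(ps.affected_fraction * config.n_samples))
        affected = rng.choice(config.n_samples, size=n_affected, replace=False)
        rows = [gene_idx[g] for g in ps.genes]
        mu[np.ix_(rows, affected)] *= 2.0 ** ps.delta
        truth.iloc[affected, truth.columns.get_loc(ps.name)] = True

    disp = config.nb_dispersion
    if disp > 0:
        n_param = 1.0 / disp
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = rng.poisson(mu)
    return (pd.DataFrame(counts, index=genes, columns=samples), truth)


def simulate_dose_response(
    config: SimulationConfig, model_id: str,
) -> list[DoseResponseExperiment]:
    """Paired targeted/control titrations for one model.

    Returns ``2 × n_experiments`` experiments: the targeted agent
    follows the model's 4PL curve, the control follows the shared
    near-flat control curve; replicate noise is Gaussian (sd =
    ``noise_sd`` viability points) truncated at 0 only.
    """
    if model_id not in config.hill_params:
        raise ValueError(f"no hill_params defined for model {model_id!r}")
    rng = _rng(config, "dose_response", model_id)
    doses = np.asarray(config.dose_grid)
    out = []
    for k in range(config.n_experiments):
        for agent, hp in ((Agent.TARGETED, config.hill_params[model_id]),
                          (Agent.CONTROL, CONTROL_CURVE)):
            truth = four_pl(doses, hp.top, hp.bottom, hp.ic50, hp.slope)
            noise = rng.normal(0.0, config.noise_sd,
                               size=(doses.size, config.replicates))
            viab = np.clip(truth[:, None] + noise, 0.0, None)
            out.append(DoseResponseExperiment(
                model_id=model_id, agent=agent, doses=doses,
                viability=viab, experiment_id=f"exp{k + 1}"))
    return out


_GENOTYPE_COLUMN = {"RB1": "RB1_state", "TP53": "TP53_state",
                    "ATR": "ATR_state", "CHD1": "CHD1_state"}
_ALTERED_STATE = {"RB1": "biallelic_loss", "TP53": "altered",
                  "ATR": "altered", "CHD1": "altered"}


def simulate_cohort(config: SimulationConfig, n: int) -> pd.DataFrame:
    """Clinical-style cohort table of n samples.

    Genotype alterations are independent Bernoulli draws at the
    configured marginal frequencies; SLFN11 expression comes from the
    two-component Gaussian mixture; tumor content is Beta-distributed.
    """
    missing = {"RB1", "TP53", "ATR", "CHD1"} - set(config.genotype_freqs)
    if missing:
        raise ValueError(f"genotype_freqs missing {sorted(missing)}")
    rng = _rng(config, "cohort")
    a, b = config.tumor_content_beta
    table = pd.DataFrame({
        "sample_id": [f"P{i:05d}-T1" for i in range(n)],
        "patient_id": [f"P{i:05d}" for i in range(n)],
        "tumor_content": rng.beta(a, b, size=n),
    })
    for gene, freq in config.genotype_freqs.items():
        altered = rng.random(n) < freq
        table[_GENOTYPE_COLUMN[gene]] = np.where(
            altered, _ALTERED_STATE[gene], "wt")
    low, high, sd, frac = config.slfn11_mixture
    positive = rng.random(n) < frac
    table["SLFN11_expr"] = rng.normal(np.where(positive, high, low), sd)
    table["SLFN11_true"] = positive
    return table


def simulate_ihc(config: SimulationConfig) -> pd.DataFrame:
    """Triplicate-core IHC table: one block of tumors per profile.

    With ``ihc_concentration`` set, each core's percentages are drawn
    from a Dirichlet centred on the profile (support restricted to the
    profile's nonzero intensities); otherwise cores carry the exact
    profile. Percentages always sum to 100 per core.
    """
    rng = _rng(config, "ihc")
    rows = []
    t = 0
    for profile in config.ihc_profiles:
        for _ in range(config.ihc_tumors_per_profile):
            tumor_id = f"T{t:03d}"
            t += 1
            for c in range(3):
                if config.ihc_concentration is None:
                    pct = np.asarray(profile, dtype=float)
                else:
                    pct = np.zeros(4)
                    pos = np.asarray(profile) > 0
                    alpha = (np.asarray(profile)[pos] / 100.0
                             * config.ihc_concentration)
                    pct[pos] = rng.dirichlet(alpha) * 100.0
                rows.append({"tumor_id": tumor_id, "core_id": f"core{c + 1}",
                             "pct0": pct[0], "pct1": pct[1],
                             "pct2": pct[2], "pct3": pct[3],
                             "evaluable": True})
    return pd.DataFrame(rows)
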