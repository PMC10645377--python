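#!/usr/bin/env python
"""Generate every synthetic pipeline input used by the later steps.

Writes (under results/simulated/): a raw-count expression matrix with
planted signature shifts and its truth table, paired targeted/control
viability titrations for all 26 panel models, a 328-sample clinical
cohort table, and a triplicate-core IHC table.
"""

from pathlib import Path

from b7h3adc import io
from b7h3adc.models import default_config
from b7h3adc.signatures import GeneSet
from b7h3adc.simulate import (PlantedSet, gene_names, simulate_cohort,
                              simulate_dose_response, simulate_expression,
                              simulate_ihc)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 0

genes = gene_names(2000)
planted = (
    PlantedSet("REPSTRESS_UP", tuple(genes[0:50]), 1.5, 0.35),
    PlantedSet("IFN_RESPONSE", tuple(genes[50:100]), 1.0, 0.40),
    PlantedSet("AR_SIGNALING", tuple(genes[100:150]), 2.0, 0.70),
)
cfg = default_config(seed=SEED, planted_sets=planted)

counts, truth = simulate_expression(cfg)
io.atomic_write_text(OUT / "counts.tsv", counts.to_csv(sep="\t"))
io.atomic_write_text(OUT / "planted_truth.tsv", truth.to_csv(sep="\t"))
io.write_gmt([GeneSet(ps.name, frozenset(ps.genes)) for ps in planted],
             OUT / "signatures.gmt")
print(f"expression: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"{len(planted)} planted sets")

experiments = [e for model in sorted(cfg.hill_params)
               for e in simulate_dose_response(cfg, model)]
io.write_dose_response(experiments, OUT / "curves.csv")
print(f"dose-response: {len(cfg.hill_params)} models x "
      f"{cfg.n_experiments} experiment pairs, {cfg.replicates} replicates "
      f"at {len(cfg.dose_grid)} doses (noise sd {cfg.noise_sd}%)")

cohort = simulate_cohort(cfg, 328)
io.write_cohort(cohort, OUT / "cohort.csv")
print(f"cohort: {len(cohort)} samples "
      f"({(cohort['tumor_content'] >= 0.3).sum()} with >= 30% tumor content)")

ihc = simulate_ihc(cfg)
io.atomic_write_text(OUT / "ihc_cores.csv", ihc.to_csv(index=False))
print(f"IHC: {ihc['tumor_id'].nunique()} tumors x 3 cores")
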