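"""Derive PRS weights from a simulated GWAS with the LD-aware penalized
regression, tune (s, lambda) on a held-out cohort, and score individuals."""

import numpy as np

from copdprs import (
    SimConfig, TuningGrid, compute_ld_blocks, score_individuals,
    simulate_gwas_sumstats, simulate_ld_genotypes, simulate_lung_phenotypes,
    tune_hyperparameters,
)

# training cohort: run the GWAS that supplies summary statistics
train = SimConfig(n_individuals=5000, n_variants=500, seed=2, architecture_seed=2)
G = simulate_ld_genotypes(train)
ph = simulate_lung_phenotypes(G, train)
ss = simulate_gwas_sumstats(G, ph["fev1_pct_pred"].to_numpy(), "FEV1")

# LD reference panel and tuning cohort share the genetic architecture
panel = simulate_ld_genotypes(SimConfig(n_individuals=500, n_variants=500, seed=3, architecture_seed=2))
blocks = compute_ld_blocks(panel, block_assignment=train.block_size)

tune_cfg = SimConfig(n_individuals=2000, n_variants=500, seed=4, architecture_seed=2)
G_t = simulate_ld_genotypes(tune_cfg)
ph_t = simulate_lung_phenotypes(G_t, tune_cfg)

grid = TuningGrid(s_values=(0.2, 0.5, 0.9, 1.0), lambda_values=(0.003, 0.01, 0.03, 0.1))
weights, report = tune_hyperparameters(ss, blocks, G_t, ph_t, grid)
print(f"selected shrinkage s={weights.s}, lambda={weights.lam}, "
      f"{len(weights)} variants with non-zero weight")

prof = score_individuals(G_t, weights, cohort="tuning")
r2 = np.corrcoef(prof.raw, ph_t["fev1_pct_pred"])[0, 1] ** 2
print(f"tuning-cohort variance explained: {100 * r2:.1f}%")
# The score is a weighted dosage sum; r2 is the squared correlation between
# the score and the trait it was trained on, in a cohort not used for the GWAS.
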