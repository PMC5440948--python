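"""Haplotype-copying imputation: panel mode and within-cohort refinement.

Part 1 masks every 20th site of a target set and imputes it back from a
matched reference panel (dosage R^2 is the accuracy metric).  Part 2
refines all genotypes of a low-coverage cohort from genotype likelihoods
alone, filling cells with zero sequencing coverage.
"""

import numpy as np

from exlwgs import calling, evaluate, reads
from exlwgs.cohort import PopulationSpec, StratumSpec, assemble_cohort
from exlwgs.impute import HaplotypePanel, impute_masked_sites, refine_cohort_genotypes

coh = assemble_cohort(
    strata=[StratumSpec("pop", 100, (1.0,), {"M": 1.0})],
    populations=[PopulationSpec("P0", 0.015, 10)],
    n_sites=2000,
    region_length=2_000_000,
    seed=21,
)
positions = coh.sites["position"].to_numpy()

# --- panel imputation with the every-20th-site holdout -------------------
targets = np.arange(25)
rest = np.arange(25, 100)
panel = HaplotypePanel(
    coh.haplotypes[np.sort(np.r_[2 * rest, 2 * rest + 1])], positions
)
design = evaluate.holdout_every_kth(positions, positions, positions, k=20)
masked = np.flatnonzero(np.isin(positions, design.masked_positions))
dosages = impute_masked_sites(coh.genotypes()[targets], masked, panel, seed=22)
truth = coh.genotypes()[targets][:, masked].astype(float)
r2 = evaluate.dosage_r2(dosages, truth)
print(f"masked {len(masked)} sites ({100 * design.masked_fraction:.1f}%), "
      f"panel of {panel.n_haplotypes} haplotypes -> dosage R^2 = {r2:.3f}")

# --- within-cohort refinement at 1.6x ------------------------------------
pileup = reads.simulate_cohort_pileups(coh, reads.DepthModel(), seed=23)
gl = calling.genotype_likelihoods_from_counts(pileup.n_ref, pileup.n_alt, 0.005)
geno, _ = refine_cohort_genotypes(gl, seed=24)
truth_all = coh.genotypes().T
report = evaluate.genotype_discordance(geno, truth_all, depth=pileup.depth)
print(f"overall discordance after refinement: {100 * report['overall']:.2f}%")
strata = report["strata"]
zero_het = strata.query("truth == 'het' and depth == 'zero'")
print(f"zero-coverage heterozygote accuracy: "
      f"{100 * zero_het['accuracy'].iloc[0]:.1f}% "
      f"({int(zero_het['n_cells'].iloc[0])} cells)")
# Cells with no reads at all are recovered from linkage alone: the copying
# model borrows haplotype segments from the rest of the cohort.
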