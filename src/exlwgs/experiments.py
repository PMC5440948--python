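"""End-to-end simulation experiments at the package's study conditions.

Each function simulates a cohort under the default generative model,
runs the relevant pipeline stage(s), and returns the headline metric(s).
These are the canonical desk-scale experiments behind the package's
performance claims: consensus-calling sensitivity/FDR at MAF >= 10%,
zero-coverage heterozygote accuracy after LD refinement, matched-panel
holdout imputation R^2, and the F_ST / Ti-Tv estimator recoveries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from exlwgs import calling, cohort, evaluate, impute, reads
from exlwgs._rng import derive_rng, derive_seed
from exlwgs.popgen import weir_cockerham_fst


def _single_population_cohort(
    seed,
    n_samples,
    n_sites=5000,
    region_length=5_000_000,
    n_founders=20,
    switch_rate=0.005,
    fst_param=0.015,
):
    """One-population founder-mosaic cohort at the default coverage spread."""
    strata = [cohort.StratumSpec("pop", n_samples, (1.0,), {"M": 1.0})]
    pops = [cohort.PopulationSpec("P0", fst_param, n_founders)]
    return cohort.assemble_cohort(
        strata=strata,
        populations=pops,
        n_sites=n_sites,
        region_length=region_length,
        switch_rate=switch_rate,
        seed=seed,
    )


def consensus_calling_experiment(
    seed: int,
    n_samples: int = 100,
    n_true_sites: int = 5000,
    n_total_positions: int = 50_000,
    region_length: int = 5_000_000,
    error_rate: float = 0.005,
    config: calling.CallerConfig | None = None,
):
    """Consensus calling sensitivity and FDR at MAF >= 10%.

    Simulates a low-coverage cohort with ``n_true_sites`` true variants,
    then runs site discovery over ``n_total_positions`` candidate
    positions (true variants plus monomorphic positions whose only
    alternate reads are sequencing errors), takes the two-caller
    consensus, filters to MAF >= 10%, and scores against truth sites
    whose cohort MAF is >= 10%.

    Returns dict(sensitivity_pct, fdr_pct, n_called, n_truth_common).
    """
    config = config or calling.CallerConfig(error_rate=error_rate)
    coh = _single_population_cohort(
        derive_seed(seed, "cohort"), n_samples, n_sites=n_true_sites,
        region_length=region_length,
    )
    rng = derive_rng(seed, "positions")

    # candidate position grid: true variant sites + monomorphic filler
    true_pos = coh.sites["position"].to_numpy()
    n_mono = n_total_positions - n_true_sites
    free = np.setdiff1d(np.arange(1, region_length + 1), true_pos)
    mono_pos = np.sort(rng.choice(free, size=n_mono, replace=False))
    mono_sites = cohort.draw_ancestral_sites(
        n_mono, region_length, seed=derive_rng(seed, "mono-alleles")
    )
    mono_table = pd.DataFrame(
        {
            "position": mono_pos,
            "ref": mono_sites["ref"].to_numpy(),
            "alt": mono_sites["alt"].to_numpy(),
        }
    )
    site_table = pd.concat(
        [coh.sites[["position", "ref", "alt"]], mono_table], ignore_index=True
    ).sort_values("position", ignore_index=True)
    is_true = np.isin(site_table["position"].to_numpy(), true_pos)

    genotypes = np.zeros((n_samples, len(site_table)), dtype=np.int8)
    genotypes[:, is_true] = coh.genotypes()
    pileup = reads.simulate_pileups(
        genotypes,
        coh.samples["target_coverage"].to_numpy(),
        error_rate=error_rate,
        seed=derive_rng(seed, "pileup"),
    )
    cs_a, cs_b = calling.call_cohort(
        pileup, site_table, coh.samples["id"], config=config
    )
    consensus = calling.consensus_merge(cs_a, cs_b)
    final = calling.maf_filter(consensus, 0.10)

    truth_maf = np.minimum(
        genotypes[:, is_true].mean(axis=0) / 2.0,
        1 - genotypes[:, is_true].mean(axis=0) / 2.0,
    )
    truth_common = set(site_table["position"].to_numpy()[is_true][truth_maf >= 0.10].tolist())
    called = set(final.sites["position"].tolist())
    truth_all = set(site_table["position"].to_numpy()[is_true].tolist())
    tp = len(called & truth_common)
    sens = tp / len(truth_common) if truth_common else float("nan")
    fdr = len(called - truth_all) / len(called) if called else float("nan")
    return {
        "sensitivity_pct": 100.0 * sens,
        "fdr_pct": 100.0 * fdr,
        "n_called": len(called),
        "n_truth_common": len(truth_common),
    }


def refinement_experiment(
    seed: int,
    n_samples: int = 200,
    n_sites: int = 5000,
    n_founders: int = 20,
    switch_rate: float = 0.005,
    n_iter: int = 10,
    params: impute.HmmParams | None = None,
):
    """Zero-coverage heterozygote accuracy after within-cohort refinement.

    Simulates a high-LD cohort at ~1.6x, refines genotypes from GLs for
    ``n_iter`` iterations, and reports the fraction of truly heterozygous,
    zero-depth cells that are called heterozygous (plus overall
    discordance).
    """
    params = params or impute.HmmParams()
    coh = _single_population_cohort(
        derive_seed(seed, "cohort"), n_samples, n_sites=n_sites,
        n_founders=n_founders, switch_rate=switch_rate,
    )
    truth = coh.genotypes().T  # (M, N)
    pileup = reads.simulate_cohort_pileups(
        coh, reads.DepthModel(), seed=derive_rng(seed, "pileup")
    )
    gl = calling.genotype_likelihoods_from_counts(
        pileup.n_ref, pileup.n_alt, 0.005
    )
    geno, _ = impute.refine_cohort_genotypes(
        gl, params=params, n_iter=n_iter, seed=derive_rng(seed, "refine")
    )
    disc = evaluate.genotype_discordance(geno, truth, depth=pileup.depth)
    strata = disc["strata"]
    het_zero = strata[(strata["truth"] == "het") & (strata["depth"] == "zero")]
    acc = float(het_zero["accuracy"].iloc[0])
    return {
        "zero_cov_het_accuracy_pct": 100.0 * acc,
        "overall_discordance_pct": 100.0 * disc["overall"],
        "n_zero_cov_het_cells": int(het_zero["n_cells"].iloc[0]),
    }


def holdout_imputation_experiment(
    seed: int,
    n_samples: int = 150,
    n_targets: int = 50,
    n_sites: int = 5000,
    k: int = 20,
    params: impute.HmmParams | None = None,
):
    """Matched-panel every-k-th-site holdout imputation R^2.

    One population; ``n_targets`` samples are imputation targets, the rest
    form the reference panel (phased haplotypes).  Every k-th site of the
    site intersection is masked and imputed; returns the dosage R^2 over
    all masked cells and the masked fraction.
    """
    params = params or impute.HmmParams()
    coh = _single_population_cohort(
        derive_seed(seed, "cohort"), n_samples, n_sites=n_sites
    )
    rng = derive_rng(seed, "split")
    targets = rng.choice(n_samples, size=n_targets, replace=False)
    rest = np.setdiff1d(np.arange(n_samples), targets)
    positions = coh.sites["position"].to_numpy()
    design = evaluate.holdout_every_kth(positions, positions, positions, k=k)
    masked_idx = np.flatnonzero(np.isin(positions, design.masked_positions))

    hap_rows = np.sort(np.concatenate([2 * rest, 2 * rest + 1]))
    panel = impute.HaplotypePanel(
        haplotypes=coh.haplotypes[hap_rows], positions=positions
    )
    target_g = coh.genotypes()[targets]  # (T, M)
    dosages = impute.impute_masked_sites(
        target_g, masked_idx, panel, params=params, seed=derive_rng(seed, "phase")
    )
    truth = target_g[:, masked_idx].astype(float)
    return {
        "dosage_r2": evaluate.dosage_r2(dosages, truth),
        "masked_fraction_pct": 100.0 * design.masked_fraction,
        "n_masked_sites": len(masked_idx),
    }


def refinement_oracle_experiment(
    seed: int,
    n_samples: int = 200,
    n_sites: int = 5000,
    n_founders: int = 20,
    switch_rate: float = 0.005,
):
    """Zero-coverage heterozygote accuracy ceiling with oracle founders.

    Identical simulation to :func:`refinement_experiment`, but the copying
    chains run against the *true* founder haplotypes instead of learning
    them -- separating the inference cost of unsupervised founder recovery
    from the irreducible switch-point ambiguity of the mosaic process.
    """
    from exlwgs.impute import _genotype_posterior, _run_chain

    coh = _single_population_cohort(
        derive_seed(seed, "cohort"), n_samples, n_sites=n_sites,
        n_founders=n_founders, switch_rate=switch_rate,
    )
    truth = coh.genotypes().T
    pileup = reads.simulate_cohort_pileups(
        coh, reads.DepthModel(), seed=derive_rng(seed, "pileup")
    )
    gl = calling.genotype_likelihoods_from_counts(
        pileup.n_ref, pileup.n_alt, 0.005
    )
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True)).transpose(1, 0, 2)
    lik = np.ascontiguousarray(lik, dtype=np.float32)
    founders = np.clip(coh.founder_panels[0].astype(float), 1e-4, 1 - 1e-4)
    dosage0 = (lik / lik.sum(-1, keepdims=True) @ np.array([0.0, 1.0, 2.0])) / 2.0
    ext1 = dosage0.copy()
    ext2 = dosage0.copy()
    for _ in range(4):
        ext1 = _run_chain(founders, lik, ext2, switch_rate)
        ext2 = _run_chain(founders, lik, ext1, switch_rate)
    post = _genotype_posterior(ext1, ext2, lik)
    geno = post.argmax(axis=-1).astype(np.int8).T
    zero_het = (pileup.depth == 0) & (truth == 1)
    acc = float((geno[zero_het] == 1).mean())
    return {
        "zero_cov_het_accuracy_pct": 100.0 * acc,
        "overall_discordance_pct": 100.0 * float((geno != truth).mean()),
    }


def fst_recovery_experiment(
    seed: int,
    fst_param: float = 0.015,
    n_sites: int = 20_000,
    n_per_pop: int = 50,
):
    """Weir-Cockerham recovery of the Balding-Nichols F parameter.

    Unlinked sites, ancestral frequencies Uniform(0.05, 0.95), two
    populations at the given F, ``n_per_pop`` diploids each sampled under
    HWE from the population frequencies.  Returns the weighted estimate.
    """
    rng = derive_rng(seed, "fst")
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    geno = np.empty((2 * n_per_pop, n_sites), dtype=np.int8)
    labels = np.array(["pop1"] * n_per_pop + ["pop2"] * n_per_pop)
    for i in range(2):
        freqs = cohort.derive_population_frequencies(anc, fst_param, seed=rng)
        block = rng.binomial(2, freqs[None, :], size=(n_per_pop, n_sites))
        geno[i * n_per_pop : (i + 1) * n_per_pop] = block
    _, w = weir_cockerham_fst(geno, labels, ("pop1", "pop2"))
    return {"fst": w}


def titv_recovery_experiment(seed: int, n_sites: int = 100_000, titv_odds: float = 2.09):
    """Ti/Tv ratio of a site table drawn at the given transition odds."""
    sites = cohort.draw_ancestral_sites(
        n_sites, 10 * n_sites, titv_odds=titv_odds, seed=derive_rng(seed, "sites")
    )
    return {"titv": calling.titv_ratio(sites)}
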