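"""Stage orchestration: simulate -> call -> impute -> popgen -> evaluate.

Each stage reads only persisted intermediates from the output directory
and derives its randomness from the master seed plus its stage name, so
re-running a stage in a fresh process reproduces a single-process
pipeline run bit for bit.  A resolved-config echo (with all derived
stage seeds) is written on every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from exlwgs import calling, cohort, evaluate, impute, popgen, reads, vcfio
from exlwgs._rng import derive_rng, derive_seed

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "impute", "popgen", "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline configuration (all parameter blocks + master seed)."""

    seed: int = 0
    outdir: str = "exlwgs_run"
    n_sites: int = 5000
    region_length: int = 5_000_000
    n_samples: int | None = None  # None -> the default 16/69/62/38 strata
    switch_rate: float = 0.005
    n_founders: int = 20
    fst_param: float = 0.015
    coverage_mean: float = 1.6
    coverage_min: float = 0.84
    coverage_max: float = 3.39
    error_rate: float = 0.005
    discovery_threshold: float = 2.8
    maf_threshold: float = 0.10
    hmm_switch_prob: float = 0.01
    hmm_mismatch_prob: float = 0.005
    refine_iters: int = 10
    admixture_k: int = 3
    holdout_k: int = 20
    mt_length: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> None:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        resolved = dataclasses.asdict(self)
        resolved["stage_seeds"] = {
            st: derive_seed(self.seed, st) for st in STAGES
        }
        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh)


def _strata(config: RunConfig):
    if config.n_samples is None:
        return cohort.default_strata()
    return [
        cohort.StratumSpec("pop", config.n_samples, (1.0, 1.0, 1.0), {"M": 1.0})
    ]


def stage_simulate(config: RunConfig) -> None:
    t0 = time.time()
    config.echo()
    out = Path(config.outdir)
    pops = cohort.default_populations(
        3, fst_param=config.fst_param, n_founders=config.n_founders
    )
    coh = cohort.assemble_cohort(
        strata=_strata(config),
        populations=pops,
        n_sites=config.n_sites,
        region_length=config.region_length,
        switch_rate=config.switch_rate,
        coverage_mean=config.coverage_mean,
        coverage_min=config.coverage_min,
        coverage_max=config.coverage_max,
        mt_length=config.mt_length,
        seed=derive_seed(config.seed, "simulate"),
    )
    coh.save(out / "cohort")
    pileup = reads.simulate_cohort_pileups(
        coh,
        reads.DepthModel(error_rate=config.error_rate),
        seed=derive_rng(config.seed, "simulate:pileup"),
    )
    pileup.save(out / "pileup.npz")
    logger.info(
        "simulate: %d samples x %d sites in %.1fs",
        coh.n_samples, coh.n_sites, time.time() - t0,
    )


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}; run the '{stage}' stage first"
        )


def stage_call(config: RunConfig) -> None:
    t0 = time.time()
    out = Path(config.outdir)
    _require(out / "cohort" / "sites.tsv", "simulate", "call")
    _require(out / "pileup.npz", "simulate", "call")
    coh = cohort.Cohort.load(out / "cohort")
    pileup = reads.PileupMatrix.load(out / "pileup.npz")
    cfg = calling.CallerConfig(
        discovery_threshold=config.discovery_threshold,
        error_rate=config.error_rate,
    )
    cs_a, cs_b = calling.call_cohort(
        pileup, coh.sites, coh.samples["id"], config=cfg
    )
    consensus = calling.consensus_merge(cs_a, cs_b)
    final = calling.maf_filter(consensus, config.maf_threshold)
    logger.info(
        "call: A=%d B=%d consensus=%d MAF>=%.2f=%d sites",
        cs_a.n_sites, cs_b.n_sites, consensus.n_sites,
        config.maf_threshold, final.n_sites,
    )
    vcfio.write_vcf(cs_a, out / "calls_A.vcf")
    vcfio.write_vcf(cs_b, out / "calls_B.vcf")
    # persist GLs for the retained sites for downstream refinement
    keep = np.isin(coh.sites["position"].to_numpy(), final.sites["position"].to_numpy())
    gl = calling.genotype_likelihoods_from_counts(
        pileup.n_ref[keep], pileup.n_alt[keep], config.error_rate
    )
    vcfio.write_vcf(final, out / "calls_consensus.vcf", gls=gl)
    np.savez_compressed(out / "call_gl.npz", gl=gl, kept=keep,
                        depth=pileup.depth[keep])
    logger.info("call stage done in %.1fs", time.time() - t0)


def stage_impute(config: RunConfig) -> None:
    t0 = time.time()
    out = Path(config.outdir)
    _require(out / "calls_consensus.vcf", "call", "impute")
    final, _ = vcfio.read_vcf(out / "calls_consensus.vcf")
    arrs = np.load(out / "call_gl.npz")
    params = impute.HmmParams(config.hmm_switch_prob, config.hmm_mismatch_prob)
    geno, dosage = impute.refine_cohort_genotypes(
        arrs["gl"],
        params=params,
        n_iter=config.refine_iters,
        seed=derive_rng(config.seed, "impute"),
    )
    refined = calling.CallSet(
        sites=final.sites, genotypes=geno, dosages=dosage,
        sample_ids=final.sample_ids,
    )
    vcfio.write_vcf(refined, out / "calls_refined.vcf")
    logger.info("impute: refined %d sites in %.1fs", refined.n_sites, time.time() - t0)


def stage_popgen(config: RunConfig) -> None:
    t0 = time.time()
    out = Path(config.outdir)
    _require(out / "calls_refined.vcf", "impute", "popgen")
    refined, _ = vcfio.read_vcf(out / "calls_refined.vcf")
    coh = cohort.Cohort.load(out / "cohort")
    labels = coh.samples["stratum"].to_numpy()
    g = refined.genotypes.T  # (N, M)

    if len(np.unique(labels)) >= 2:
        names, fmat = popgen.fst_matrix(g, labels)
        pd.DataFrame(fmat, index=names, columns=names).to_csv(
            out / "fst_matrix.tsv", sep="\t"
        )
    coords, frac = popgen.pca_genotype(g, n_components=5)
    pca = pd.DataFrame(
        coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    pca.insert(0, "id", coh.samples["id"])
    with open(out / "pca.tsv", "w") as fh:
        fh.write("# variance_fractions: " + ",".join(f"{v:.5f}" for v in frac) + "\n")
        pca.to_csv(fh, sep="\t", index=False)
    kept = popgen.ld_prune(g)
    q, _, ll = popgen.admixture_em(
        g[:, kept], config.admixture_k, seed=derive_rng(config.seed, "popgen")
    )
    qdf = pd.DataFrame(q, columns=[f"Q{i+1}" for i in range(q.shape[1])])
    qdf.insert(0, "stratum", labels)
    qdf.insert(0, "id", coh.samples["id"])
    qdf.to_csv(out / "admixture_q.tsv", sep="\t", index=False)
    logger.info(
        "popgen: %d pruned sites, admixture loglik %.1f, %.1fs",
        len(kept), ll, time.time() - t0,
    )


def stage_evaluate(config: RunConfig) -> None:
    t0 = time.time()
    out = Path(config.outdir)
    _require(out / "calls_refined.vcf", "impute", "evaluate")
    coh = cohort.Cohort.load(out / "cohort")
    refined, _ = vcfio.read_vcf(out / "calls_refined.vcf")
    consensus, _ = vcfio.read_vcf(out / "calls_consensus.vcf")
    arrs = np.load(out / "call_gl.npz")
    truth_g = coh.genotypes().T  # (M, N)
    positions = coh.sites["position"].to_numpy()
    truth_maf = np.minimum(
        truth_g.mean(axis=1) / 2.0, 1 - truth_g.mean(axis=1) / 2.0
    )

    report = {}
    sens = evaluate.call_set_sensitivity_fdr(
        consensus.sites["position"].to_numpy(),
        consensus.called_maf(),
        positions[truth_maf >= config.maf_threshold],
        truth_maf[truth_maf >= config.maf_threshold],
    )
    sens.to_csv(out / "sensitivity_fdr.tsv", sep="\t", index=False)
    overall = sens[sens["overall"]].iloc[0]
    report["sensitivity"] = overall["sensitivity"]
    report["fdr"] = overall["fdr"]

    kept = arrs["kept"]
    disc = evaluate.genotype_discordance(
        refined.genotypes, truth_g[kept], depth=arrs["depth"]
    )
    report["overall_discordance"] = disc["overall"]
    disc["strata"].to_csv(out / "discordance_strata.tsv", sep="\t", index=False)
    het_zero = disc["strata"].query("truth == 'het' and depth == 'zero'")
    report["zero_cov_het_accuracy"] = float(het_zero["accuracy"].iloc[0])

    mito = evaluate.mito_cohort_summary(
        coh, reads.DepthModel(error_rate=config.error_rate),
        table=evaluate.synthetic_haplogroup_table(mt_length=coh.mt_length),
        seed=derive_rng(config.seed, "evaluate:mito"),
    )
    mito["proportions"].to_csv(out / "haplogroup_proportions.tsv", sep="\t")
    report["mean_mito_depth"] = float(mito["mean_depths"].mean())

    with open(out / "report.json", "w") as fh:
        json.dump({k: float(v) for k, v in report.items()}, fh, indent=2)
    logger.info("evaluate stage done in %.1fs", time.time() - t0)


def run_pipeline(config: RunConfig) -> dict:
    for stage in (
        stage_simulate, stage_call, stage_impute, stage_popgen, stage_evaluate
    ):
        stage(config)
    with open(Path(config.outdir) / "report.json") as fh:
        return json.load(fh)
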