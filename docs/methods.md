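# Methods

This note documents the generative models, estimators and numerical choices
behind `exlwgs`, in the spirit of a methods supplement: what is modelled, why
the defaults are what they are, and what the simulation does and does not
tell you about real data.

## 1. Cohort simulation

### Sites and mutation spectrum

Biallelic SNVs are placed uniformly without replacement on a single linear
contig (default 5,000 sites on 5 Mb) with strictly increasing 1-based
positions. Each site is a transition (A↔G, C↔T) with probability
odds/(1+odds); the default odds of 2.09 make the site spectrum's Ti/Tv ratio
match the ~2.1 genome-wide value expected of a sound human call set.
Ancestral allele frequencies are Uniform(0.05, 0.95): the package's analyses
target common variation (MAF ≥ 10%), so simulating a realistic rare-variant
site frequency spectrum is out of scope.

### Population differentiation

Population allele frequencies drift from the ancestral ones under
Balding–Nichols: freq ~ Beta(p(1−F)/F, (1−p)(1−F)/F), giving E[freq] = p and
Var = F·p(1−p). This is the standard single-parameter differentiation model
and the reason the F_ST recovery tests are exact: Weir–Cockerham's estimator
targets precisely this F. The default F = 0.015 reproduces the mean pairwise
differentiation of closely related strata within one geographic region;
F = 0 returns the ancestral frequencies exactly (degenerate Beta).

### Linkage disequilibrium

LD is generated by **founder-mosaic copying** rather than coalescent
simulation: each population has a small founder panel (default 20 haplotypes,
drawn site-independently at the population frequencies), and each sampled
haplotype follows a hidden Markov path over founders — at every site, with
probability `switch_rate` (default 0.005) the template is redrawn
(population ~ the individual's admixture vector q, founder uniform within
population). Mosaic segments therefore average 1/switch_rate = 200 sites.
This is desk-scale, exactly controllable (LD strength = founder count and
switch rate), and matches the model class the imputation stage assumes. It
does **not** reproduce a recombination map, allele-age–dependent LD decay, or
rare haplotypes private to one individual; accuracy numbers on this LD
structure are therefore analogs of, not predictions for, real genomes.

### Strata, coverage, mtDNA

The default cohort has four social strata of 16/69/62/38 individuals
(total 185) with stratum-specific Dirichlet admixture over K = 3 ancestral
components — two dominant clines plus a third component concentrated in the
tribal stratum. The exact concentrations are illustrative configuration, not
ground truth to be recovered. Per-sample target coverage is Gamma
moment-matched to mean 1.6x (sd 0.45), rejection-truncated to [0.84, 3.39];
the sd is chosen so the truncated range is actually exercised.
Each individual carries an mtDNA haplogroup label drawn from its stratum's
configured lineage distribution (the tribal stratum defaults to 100%
lineage M; lineage K only appears in the upper stratum). Haplogroup-defining
variants and the mitochondrial reference sequence are synthetic and seeded —
labels echo major lineage names, but no real phylogeny (PhyloTree etc.) is
used.

## 2. Sequencing model

Read-level detail is deliberately abstracted to per-site allele counts:
depth ~ Poisson(c) per (site, sample) cell, and each read flips its allele
with probability ε (default 0.005, symmetric, no strand or context effects).
Every downstream statistic consumes only counts and likelihoods, so
FASTQ/BAM machinery would add nothing to what is being evaluated. The
mitochondrial contig uses the same process at c × `mito_copy_factor`
(default 75, so 1.6x nuclear → ~120x mtDNA) with full 4-base counts and
errors spread uniformly over the three non-true bases.

The Poisson model implies the Lander–Waterman coverage expectations
P(depth ≥ k) = 1 − Σ_{j<k} e^{−c} c^j/j!; at c = 1.6 these are 79.8% (k=1)
and 47.5% (k=2). The two-read figure is the one the package's acceptance
checks use; the one-read figure of a real survey falls slightly below the
Poisson value because real coverage is overdispersed.

## 3. Variant calling

Genotype likelihoods are binomial in the alternate-read count with
p = (ε, ½, 1−ε) for g = (0, 1, 2), stored in natural-log space normalised to
max 0; zero-depth cells are flat. Per-site allele frequencies are estimated
by EM under Hardy–Weinberg across all samples (joint calling: at 1.6x the
information is in the population, not the individual). The EM is tested for
oracle equivalence against a 10⁻⁴-grid likelihood maximiser.

Site discovery runs two deliberately different callers:

* **Caller A (LRT)**: Λ = log L(f̂) − max(log L(f=0), log L(f=1)) under the
  HWE-mixture likelihood, called when Λ ≥ s. The default s = 2.8 echoes the
  variance-ratio tuning point of GL-based callers; a tuning utility
  (`tune_discovery_threshold`) reproduces the procedure of choosing s on a
  training replicate to bound FDR.
* **Caller B (hard filter)**: at least `min_alt_samples` (2) samples with at
  least `min_alt_reads` (2) alternate reads, and pooled alternate fraction in
  [3ε, 1−3ε].

The consensus is the (position, ref, alt) intersection with genotypes taken
from caller A; allele-mismatched positions are excluded and logged. The final
filter keeps sites with **called-genotype** MAF ≥ 10% (inclusive, like every
threshold in the package). Computing MAF from called genotypes — not truth,
not dosages — matches how a real pipeline filters and is the main reason
consensus sensitivity sits near 90% rather than near 100%: heterozygote
undercalling at 1.6x biases called MAF downward by ~0.07, pushing ~10% of
truly-common sites below the cutoff. This mirrors the recall/FDR trade a
two-pipeline consensus makes on real data.

Sample QC flags outliers in per-sample SNV counts by robust z-score
(median/MAD, MAD scaled 1.4826, falling back to mean/sd when MAD = 0) and
reports Fisher-exact batch enrichment of the flags when batch labels exist.

## 4. Imputation

### Panel mode (`impute_masked_sites`)

Li–Stephens haploid copying: stay with probability 1−switch_prob, else jump
uniformly; emission matches the template with probability 1−mismatch_prob;
missing observations emit uniformly. Defaults switch_prob = 0.01,
mismatch_prob = 0.005 — chosen once to bracket the simulator's mosaic scale
(switch 0.005/site) with a margin for model mismatch. Diploid targets are
phased by iterated conditional phasing (5 rounds): at heterozygous sites
allele 1 is assigned to the chain whose **extrinsic** (leave-site-out)
posterior supports it more. The extrinsic probability divides the site's own
emission back out of the forward–backward posterior — without this the
posterior at an observed site simply echoes the current phase and the
iteration cannot improve. Masked-site dosage is the sum of the two chains'
expected alleles, clipped to [0, 2].

### Within-cohort refinement (`refine_cohort_genotypes`)

Refinement must learn haplotype structure from 1.6x genotype likelihoods with
no reference panel. Two phases:

1. **Haplotype-cluster EM bootstrap** (default 40 sweeps, K = 30 clusters):
   each individual is two copying chains over K learned cluster haplotypes
   θ ∈ [0,1]^{K×M} (fastPHASE-style). A chain's emission at a site integrates
   the genotype likelihood over the partner chain's current allele
   distribution, so nothing is ever hard-called during learning. θ is
   initialised from randomly chosen individuals' posterior dosages plus
   noise; K is set above the simulator's founder count because surplus
   clusters absorb blended local optima.
2. **Leave-one-out panel refinement** (default 10 sweeps): the classic
   within-cohort loop — each sample's chains copy from the other samples'
   current phased haplotypes (own haplotypes masked out of the panel), with
   the same soft emissions. The panel is capped at 200 haplotypes per sweep
   by seeded resampling; ablations showed the resampled capped panel slightly
   *outperforms* the full panel while costing half as much.

The genotype posterior is extrinsic copying prior × GL, renormalised; hard
genotypes are its argmax, dosages its mean, for every cell including
zero-coverage ones. When all cells are deeply covered and certain, the GL
term dominates and output equals the GL argmax; at a single site (no LD) the
prior collapses to an allele-frequency prior and output follows GL×HWE.

**Design history and the zero-coverage ceiling.** A refinement that
hard-conditions chains on current genotype calls (the textbook iterated
scheme) cannot bootstrap at 1.6x: with ~22% initial genotype error and random
phase, the panel has no founder-segment signal to track and accuracy
stagnates. The soft-emission cluster bootstrap fixes this. Even so, the
accuracy at truly heterozygous zero-coverage cells converges to ~93% under
the default conditions (200 samples, 20 founders, 5,000 sites), not higher.
`exlwgs.experiments.refinement_oracle_experiment` runs the same simulation
with the **true** founder haplotypes supplied to the copying chains: those
cells then score ~96%, so roughly 3 points of the gap are the cost of
unsupervised founder recovery and ~4 points are switch-point ambiguity
inherent to the mosaic process itself. Real surveys quoting higher
zero-coverage heterozygote accuracy benefit from far denser sites and larger
effective panels than this desk-scale analog.

## 5. Population-genetic estimators

* **F_ST**: Weir & Cockerham (1984) two-population variance components per
  site; weighted mean Σa/Σ(a+b+c) over sites with a defined denominator;
  monomorphic-in-both sites are skipped. Invariant under ref/alt relabeling;
  small negative estimates are legitimate and preserved.
* **PCA**: centre by 2p̂, scale by √(p̂(1−p̂)) (Patterson normalisation);
  missing cells mean-imputed per site; monomorphic sites dropped with a
  logged count; no outlier iterations. Coordinates are eigenvectors scaled by
  √eigenvalue; variance fractions are over the full spectrum and sum to 1.
  GL-based analyses substitute E[g | GL, HWE(AF)] dosages for called
  genotypes.
* **LD pruning**: greedy within 50-site windows sliding by 5: for each pair
  of still-kept sites with r² strictly above 0.2 the later site is dropped;
  deterministic; r² is pairwise-complete Pearson on dosages.
* **Admixture**: EM on the binomial admixture likelihood with Q rows on the
  simplex and F clipped to [10⁻⁶, 1−10⁻⁶]; multiple seeded restarts keep the
  best likelihood. EM is slower than quasi-Newton block relaxation but
  monotone (tested) and adequate at desk scale. Component label switching is
  resolved in tests by greedy matching on F rows. K = 4–7 sweeps are
  supported; cross-validated choice of K is not.

## 6. Evaluation battery

Sensitivity per truth-MAF bin and FDR per called-MAF bin (edges
left-inclusive, defaults 0.1/0.2/0.3/0.4/0.5); genotype discordance overall,
per sample, and stratified (truth hom/het × depth zero/positive); the
every-20th-site holdout (sort the three-way site intersection, mask 1-based
indices ≡ 0 mod k, so |I| divisible by 20 masks exactly 5%); dosage R² as the
squared Pearson correlation over all masked cells (sign-blind by
construction); the custom-vs-generic panel comparison with the generic panel
simulated at configurable divergence (divergence parameterises exactly the
panel-mismatch effect the comparison measures); mitochondrial majority-rule
consensus (depth gate > 10, ties and shallow positions emit 'N', no IUPAC
codes) and haplogroup scoring (fraction of defining alleles matched;
assignments below 0.8 or tied are "unassigned").

## 7. Reproducibility and numerics

Every stochastic operation accepts an integer seed or Generator; pipeline
stages derive their seeds from master seed + stage name, so stage-wise re-runs
from persisted intermediates are bit-identical to single-process runs.
Forward–backward recursions are scaled per site (underflow-safe) and the hot
kernels are numba-compiled with O(M·K) memory per sample; posteriors are
normalised at every site (checked to 10⁻⁹ in tests). All thresholds are
inclusive (≥) except the LD-pruning r² comparison, which is strictly greater —
both documented in the config echo.

## 8. Problem sizes

The shipped experiments use 100–200 samples and 2,000–50,000 candidate
positions on one contig — sizes chosen so each experiment completes in
minutes on a single CPU while leaving the estimators' sampling error well
below the effects being measured. The full evaluation battery
(`scripts/acceptance.py`) runs in roughly 10 minutes.

## 9. Known limitations

* No recombination-map LD, no rare-variant SFS, no indels/SVs, no sex
  chromosomes, no selection; single contig.
* The error model has no strand, context or mapping effects; Ti/Tv of *false*
  calls is therefore unrealistic.
* The refinement's zero-coverage heterozygote accuracy is bounded near 93%
  under the default simulation (see §4); treat it as a lower-bound analog of
  real-data performance, not an estimate of it.
* Admixture ground-truth proportions of the default strata are illustrative;
  only the simulated-Q recovery experiment has a defined truth.
* The VCF reader/writer covers the package's own subset (GT/DS/GL, single
  contig, biallelic SNVs), not arbitrary VCF.
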