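"""Synthetic structured cohorts for low-coverage sequencing experiments.

The generative model, bottom up:

1. Ancestral biallelic SNV sites on one linear contig, with a
   transition/transversion mutation spectrum and ancestral allele
   frequencies drawn uniformly on a configurable band.
2. Per ancestral population, allele frequencies drift away from the
   ancestral frequency under the Balding-Nichols model: for ancestral
   frequency ``p`` and differentiation ``F``, the population frequency is
   Beta(p(1-F)/F, (1-p)(1-F)/F), so E[freq] = p and Var = F p(1-p).
3. Each population carries a small panel of founder haplotypes drawn
   site-independently at the population frequencies.
4. Sampled haplotypes are hidden-Markov mosaics of founders: at each site
   the copying template is kept, or with probability ``switch_rate``
   redrawn (population ~ the individual's admixture vector q, founder
   uniform within the population).  This creates the linkage
   disequilibrium that haplotype-copying imputation exploits.
5. A cohort assembles strata of individuals with stratum-specific
   Dirichlet admixture, per-sample target sequencing coverage from a
   truncated Gamma, and a mitochondrial haplogroup label drawn from the
   stratum's lineage distribution.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from exlwgs._rng import as_rng, derive_rng

# purine<->purine and pyrimidine<->pyrimidine partners
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
_BASES = np.array(["A", "C", "G", "T"])


def mutation_class(ref: str, alt: str) -> str:
    """Classify a biallelic substitution as transition or transversion."""
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    return "transition" if _TRANSITION_PARTNER[ref] == alt else "transversion"


@dataclasses.dataclass(frozen=True)
class AncestralSite:
    """One biallelic SNV site on the simulated contig (1-based position)."""

    position: int
    ref_allele: str
    alt_allele: str
    ancestral_freq: float
    mutation_class: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 < self.ancestral_freq < 1.0:
            raise ValueError("ancestral_freq must lie in (0, 1)")
        expected = mutation_class(self.ref_allele, self.alt_allele)
        if expected != self.mutation_class:
            raise ValueError(
                f"mutation_class {self.mutation_class!r} inconsistent with "
                f"{self.ref_allele}->{self.alt_allele} ({expected})"
            )


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """An ancestral population: Balding-Nichols F and founder-panel size."""

    name: str
    fst_param: float
    n_founders: int = 20

    def __post_init__(self):
        if not 0.0 <= self.fst_param < 1.0:
            raise ValueError("fst_param must lie in [0, 1)")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """One cohort stratum: size, Dirichlet admixture concentration over the
    K ancestral populations, and a categorical mtDNA haplogroup distribution."""

    name: str
    n_samples: int
    admixture_alpha: tuple
    mt_haplogroup_probs: dict

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("stratum size must be positive")
        total = sum(self.mt_haplogroup_probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"haplogroup proportions for stratum {self.name!r} sum to {total}, not 1"
            )


@dataclasses.dataclass
class Cohort:
    """A simulated cohort.

    ``haplotypes`` is a (2N, M) 0/1 matrix; rows ``2i`` and ``2i+1`` are the
    two haplotypes of individual ``i`` in ``samples`` order.  ``samples`` is a
    DataFrame with columns id, stratum, target_coverage, mt_haplogroup;
    ``sites`` has columns position, ref, alt, mutation_class, ancestral_freq.
    ``admixture_q`` holds the true per-individual ancestry proportions.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    haplotypes: np.ndarray
    admixture_q: np.ndarray
    seed: int
    mt_length: int = 16569
    # in-memory only (not serialised): the founder panels the haplotypes
    # were copied from, for oracle/ceiling analyses
    founder_panels: list | None = dataclasses.field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def genotypes(self) -> np.ndarray:
        """True diploid genotypes, (N, M) with values in {0,1,2}."""
        return (
            self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        ).astype(np.int8)

    # ---- serialization -------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        np.savez_compressed(
            outdir / "haplotypes.npz",
            haplotypes=self.haplotypes.astype(np.uint8),
            admixture_q=self.admixture_q,
        )
        with open(outdir / "cohort.yaml", "w") as fh:
            yaml.safe_dump({"seed": int(self.seed), "mt_length": int(self.mt_length)}, fh)

    @classmethod
    def load(cls, outdir) -> "Cohort":
        outdir = Path(outdir)
        sites = pd.read_csv(outdir / "sites.tsv", sep="\t")
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
        arrs = np.load(outdir / "haplotypes.npz")
        with open(outdir / "cohort.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            sites=sites,
            samples=samples,
            haplotypes=arrs["haplotypes"],
            admixture_q=arrs["admixture_q"],
            seed=meta["seed"],
            mt_length=meta["mt_length"],
        )


# ---------------------------------------------------------------------------
# site spectrum
# ---------------------------------------------------------------------------

def draw_ancestral_sites(
    n_sites: int,
    region_length: int,
    titv_odds: float = 2.09,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    seed=None,
) -> pd.DataFrame:
    """Draw biallelic SNV sites with a transition/transversion spectrum.

    Positions are sampled without replacement on [1, region_length] and
    sorted; each site is a transition with probability
    ``titv_odds / (1 + titv_odds)``; ancestral frequencies are
    Uniform(freq_low, freq_high).

    Returns a DataFrame (position, ref, alt, mutation_class, ancestral_freq).
    """
    if not 0.0 < freq_low < freq_high < 1.0:
        raise ValueError("need 0 < freq_low < freq_high < 1")
    if n_sites > region_length:
        raise ValueError(
            f"cannot place {n_sites} sites on a {region_length} bp contig"
        )
    rng = as_rng(seed)
    if n_sites == 0:
        return pd.DataFrame(
            columns=["position", "ref", "alt", "mutation_class", "ancestral_freq"]
        )
    positions = np.sort(rng.choice(region_length, size=n_sites, replace=False)) + 1
    ref = _BASES[rng.integers(0, 4, size=n_sites)]
    p_ti = titv_odds / (1.0 + titv_odds)
    is_ti = rng.random(n_sites) < p_ti
    alt = np.empty(n_sites, dtype=object)
    tv_pick = rng.integers(0, 2, size=n_sites)
    for i in range(n_sites):
        if is_ti[i]:
            alt[i] = _TRANSITION_PARTNER[ref[i]]
        else:
            alt[i] = _TRANSVERSION_PARTNERS[ref[i]][tv_pick[i]]
    freqs = rng.uniform(freq_low, freq_high, size=n_sites)
    return pd.DataFrame(
        {
            "position": positions.astype(np.int64),
            "ref": ref,
            "alt": alt,
            "mutation_class": np.where(is_ti, "transition", "transversion"),
            "ancestral_freq": freqs,
        }
    )


# ---------------------------------------------------------------------------
# population frequencies and founders
# ---------------------------------------------------------------------------

def derive_population_frequencies(
    ancestral_freq: np.ndarray, fst_param: float, seed=None
) -> np.ndarray:
    """Balding-Nichols population frequencies for one population.

    F = 0 returns the ancestral frequencies exactly; otherwise each site's
    frequency is an independent Beta(p(1-F)/F, (1-p)(1-F)/F) draw.
    """
    if not 0.0 <= fst_param < 1.0:
        raise ValueError("fst_param must lie in [0, 1)")
    p = np.asarray(ancestral_freq, dtype=float)
    if fst_param == 0.0:
        return p.copy()
    rng = as_rng(seed)
    scale = (1.0 - fst_param) / fst_param
    return rng.beta(p * scale, (1.0 - p) * scale)


def build_founder_haplotypes(
    pop_freqs: np.ndarray, n_founders: int, seed=None
) -> np.ndarray:
    """(n_founders, n_sites) 0/1 matrix; each allele an independent
    Bernoulli(pop frequency) draw."""
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = as_rng(seed)
    freqs = np.asarray(pop_freqs, dtype=float)
    return (rng.random((n_founders, freqs.size)) < freqs[None, :]).astype(np.uint8)


def sample_mosaic_haplotypes(
    founder_panels: list,
    admixture_q: np.ndarray,
    switch_rate: float = 0.005,
    seed=None,
    n_haplotypes: int = 1,
) -> np.ndarray:
    """Sample haplotypes as founder mosaics under a Markov copying path.

    ``founder_panels`` is a list of K (n_founders_k, M) matrices.  At each
    site the hidden template is kept, or with probability ``switch_rate``
    redrawn: population ~ q, founder uniform within that population.  The
    emitted allele equals the template allele (no copy error at generation
    time).  Returns an (n_haplotypes, M) 0/1 matrix.
    """
    if not founder_panels or any(p.shape[0] == 0 for p in founder_panels):
        raise ValueError("founder panels must be nonempty")
    q = np.asarray(admixture_q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("admixture proportions must sum to 1")
    if not 0.0 <= switch_rate <= 1.0:
        raise ValueError("switch_rate must lie in [0, 1]")
    rng = as_rng(seed)
    n_sites = founder_panels[0].shape[1]
    sizes = np.array([p.shape[0] for p in founder_panels])
    out = np.empty((n_haplotypes, n_sites), dtype=np.uint8)
    for h in range(n_haplotypes):
        # segment the contig at switch events; one (pop, founder) per segment
        switches = rng.random(n_sites) < switch_rate
        switches[0] = True
        seg_id = np.cumsum(switches) - 1
        n_seg = seg_id[-1] + 1
        seg_pop = rng.choice(len(founder_panels), size=n_seg, p=q)
        seg_founder = (rng.random(n_seg) * sizes[seg_pop]).astype(np.int64)
        pop_per_site = seg_pop[seg_id]
        founder_per_site = seg_founder[seg_id]
        for k, panel in enumerate(founder_panels):
            mask = pop_per_site == k
            if mask.any():
                out[h, mask] = panel[founder_per_site[mask], mask]
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def default_populations(k: int = 3, fst_param: float = 0.015, n_founders: int = 20):
    """K ancestral populations at a common Balding-Nichols F."""
    names = ["ANC%d" % i for i in range(k)]
    return [PopulationSpec(n, fst_param, n_founders) for n in names]


def default_strata() -> list:
    """Four social strata with sizes 16/69/62/38 (total 185).

    Admixture concentrations describe two dominant ancestry clines plus an
    East-Asian-like third component concentrated in the tribal stratum; the
    exact numbers are illustrative configuration, not ground truth.
    """
    return [
        StratumSpec(
            "upper", 16, (5.0, 3.0, 0.05),
            {"M": 0.55, "R": 0.20, "HV": 0.10, "U": 0.05, "K": 0.10},
        ),
        StratumSpec(
            "middle", 69, (3.0, 5.0, 0.05),
            {"M": 0.70, "R": 0.20, "U": 0.10},
        ),
        StratumSpec(
            "lower", 62, (2.0, 6.0, 0.05),
            {"M": 0.75, "R": 0.15, "U": 0.10},
        ),
        StratumSpec(
            "tribal", 38, (0.8, 5.0, 1.2),
            {"M": 1.0},
        ),
    ]


def draw_target_coverages(
    n: int,
    mean: float = 1.6,
    cov_min: float = 0.84,
    cov_max: float = 3.39,
    sd: float = 0.45,
    seed=None,
) -> np.ndarray:
    """Per-sample mean coverages: Gamma moment-matched to (mean, sd),
    rejection-truncated to [cov_min, cov_max]."""
    if not cov_min < mean < cov_max:
        raise ValueError("need cov_min < mean < cov_max")
    rng = as_rng(seed)
    shape = (mean / sd) ** 2
    scale = mean / shape
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(shape, scale, size=2 * (n - filled) + 8)
        keep = draw[(draw >= cov_min) & (draw <= cov_max)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def assemble_cohort(
    strata=None,
    populations=None,
    n_sites: int = 5000,
    region_length: int = 5_000_000,
    titv_odds: float = 2.09,
    switch_rate: float = 0.005,
    coverage_mean: float = 1.6,
    coverage_min: float = 0.84,
    coverage_max: float = 3.39,
    coverage_sd: float = 0.45,
    mt_length: int = 16569,
    seed: int = 0,
) -> Cohort:
    """Assemble a full cohort: sites, founders, mosaic haplotypes, coverages
    and mtDNA haplogroup labels, all derived from one master seed."""
    strata = strata if strata is not None else default_strata()
    populations = populations if populations is not None else default_populations()
    k = len(populations)
    for st in strata:
        if len(st.admixture_alpha) != k:
            raise ValueError(
                f"stratum {st.name!r} admixture_alpha length != {k} populations"
            )

    sites = draw_ancestral_sites(
        n_sites,
        region_length,
        titv_odds=titv_odds,
        seed=derive_rng(seed, "sites"),
    )
    anc = sites["ancestral_freq"].to_numpy()
    panels = []
    for pop in populations:
        freqs = derive_population_frequencies(
            anc, pop.fst_param, seed=derive_rng(seed, f"freqs:{pop.name}")
        )
        panels.append(
            build_founder_haplotypes(
                freqs, pop.n_founders, seed=derive_rng(seed, f"founders:{pop.name}")
            )
        )

    rng_q = derive_rng(seed, "admixture")
    rng_hg = derive_rng(seed, "haplogroups")
    ids, labels, q_rows = [], [], []
    total = sum(st.n_samples for st in strata)
    hap = np.empty((2 * total, n_sites), dtype=np.uint8)
    hap_rng = derive_rng(seed, "mosaic")
    haplogroups = []
    i = 0
    for st in strata:
        hg_names = list(st.mt_haplogroup_probs)
        hg_p = np.array([st.mt_haplogroup_probs[h] for h in hg_names])
        for j in range(st.n_samples):
            q = rng_q.dirichlet(st.admixture_alpha)
            hap[2 * i : 2 * i + 2] = sample_mosaic_haplotypes(
                panels, q, switch_rate, seed=hap_rng, n_haplotypes=2
            )
            ids.append(f"{st.name}_{j:03d}")
            labels.append(st.name)
            q_rows.append(q)
            haplogroups.append(hg_names[rng_hg.choice(len(hg_names), p=hg_p)])
            i += 1

    coverages = draw_target_coverages(
        total,
        mean=coverage_mean,
        cov_min=coverage_min,
        cov_max=coverage_max,
        sd=coverage_sd,
        seed=derive_rng(seed, "coverage"),
    )
    samples = pd.DataFrame(
        {
            "id": ids,
            "stratum": labels,
            "target_coverage": coverages,
            "mt_haplogroup": haplogroups,
        }
    )
    return Cohort(
        sites=sites,
        samples=samples,
        haplotypes=hap,
        admixture_q=np.array(q_rows),
        seed=seed,
        mt_length=mt_length,
        founder_panels=panels,
    )
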