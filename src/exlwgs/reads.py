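"""In-silico sequencing: Poisson depth, allele miscalls, coverage math.

Read-level detail (lengths, mapping, quality) is abstracted to per-site
allele counts: every downstream statistic in this package consumes only
counts and genotype likelihoods.  Depth at a site is Poisson(c) for a
sample with mean coverage c; each read reports the wrong allele with
probability epsilon (symmetric flip).  The mitochondrial contig is
modelled as the same process at ``c * mito_copy_factor`` with full
4-base counts, reflecting mtDNA's high cellular copy number.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import stats

from exlwgs._rng import as_rng

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class DepthModel:
    """Sequencing depth/error model.

    error_rate: per-base miscall probability (allele flip).
    mito_copy_factor: multiplier mapping nuclear mean coverage to
    mitochondrial mean coverage (default 75, so 1.6x nuclear -> ~120x mtDNA).
    """

    error_rate: float = 0.005
    mito_copy_factor: float = 75.0

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.mito_copy_factor < 1.0:
            raise ValueError("mito_copy_factor must be >= 1")


@dataclasses.dataclass
class PileupMatrix:
    """Per-site, per-sample reference/alternate read counts (sites x samples)."""

    n_ref: np.ndarray
    n_alt: np.ndarray

    def __post_init__(self):
        self.n_ref = np.asarray(self.n_ref)
        self.n_alt = np.asarray(self.n_alt)
        if self.n_ref.shape != self.n_alt.shape:
            raise ValueError("n_ref and n_alt shapes differ")
        if (self.n_ref < 0).any() or (self.n_alt < 0).any():
            raise ValueError("read counts must be nonnegative")

    @property
    def depth(self) -> np.ndarray:
        return self.n_ref + self.n_alt

    def save(self, path) -> None:
        np.savez_compressed(Path(path), n_ref=self.n_ref, n_alt=self.n_alt)

    @classmethod
    def load(cls, path) -> "PileupMatrix":
        arrs = np.load(Path(path))
        return cls(n_ref=arrs["n_ref"], n_alt=arrs["n_alt"])


def simulate_site_pileup(genotype: int, depth_mean: float, error_rate: float, seed=None):
    """Simulate one (site, sample) cell: depth ~ Poisson(c), alt reads ~
    Binomial(depth, p_g) with p_g = eps, 0.5, 1-eps for g = 0, 1, 2."""
    if genotype not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1 or 2")
    if depth_mean < 0:
        raise ValueError("mean depth must be nonnegative")
    rng = as_rng(seed)
    depth = rng.poisson(depth_mean)
    p_alt = (error_rate, 0.5, 1.0 - error_rate)[genotype]
    n_alt = rng.binomial(depth, p_alt) if depth > 0 else 0
    return depth - n_alt, n_alt


def simulate_pileups(
    genotypes: np.ndarray,
    target_coverage: np.ndarray,
    error_rate: float = 0.005,
    seed=None,
) -> PileupMatrix:
    """Vectorised pileup simulation for a genotype matrix.

    genotypes: (N samples, M sites) in {0,1,2}; target_coverage: (N,).
    Returns a PileupMatrix with (M, N) count matrices; cells independent.
    """
    rng = as_rng(seed)
    g = np.asarray(genotypes)
    n, m = g.shape
    cov = np.broadcast_to(np.asarray(target_coverage, dtype=float)[:, None], (n, m))
    depth = rng.poisson(cov)
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])[g]
    n_alt = rng.binomial(depth, p_alt)
    return PileupMatrix(n_ref=(depth - n_alt).T, n_alt=n_alt.T)


def simulate_cohort_pileups(cohort, depth_model: DepthModel, seed=None) -> PileupMatrix:
    """Pileups for a whole cohort at its per-sample target coverages."""
    return simulate_pileups(
        cohort.genotypes(),
        cohort.samples["target_coverage"].to_numpy(),
        error_rate=depth_model.error_rate,
        seed=seed,
    )


def prob_depth_at_least(c: float, k: int) -> float:
    """Lander-Waterman / Poisson probability that a base at mean coverage c
    is covered by at least k reads: 1 - sum_{j<k} e^-c c^j / j!."""
    if c < 0:
        raise ValueError("mean coverage must be nonnegative")
    if not float(k).is_integer() or k < 0:
        raise ValueError("k must be a nonnegative integer")
    k = int(k)
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, c))


def simulate_mito_pileup(
    mt_sequence: str,
    nuclear_coverage: float,
    depth_model: DepthModel,
    seed=None,
) -> np.ndarray:
    """Per-position base counts for the mitochondrial contig.

    Depth at each position ~ Poisson(nuclear_coverage * mito_copy_factor);
    each read reports the true base with probability 1 - eps, otherwise a
    uniformly chosen different base.  Returns an (L, 4) count matrix in
    A, C, G, T order.
    """
    rng = as_rng(seed)
    eps = depth_model.error_rate
    length = len(mt_sequence)
    depth = rng.poisson(nuclear_coverage * depth_model.mito_copy_factor, size=length)
    true_idx = np.array([_BASE_INDEX[b] for b in mt_sequence])
    counts = np.zeros((length, 4), dtype=np.int64)
    n_err = rng.binomial(depth, eps)
    counts[np.arange(length), true_idx] = depth - n_err
    # errors split uniformly over the three non-true bases
    err_split = rng.multinomial(n_err, [1 / 3] * 3)
    other = np.argsort(
        np.eye(4)[true_idx], axis=1, kind="stable"
    )[:, :3]  # the 3 indices != true base, ascending
    for j in range(3):
        counts[np.arange(length), other[:, j]] += err_split[:, j]
    return counts
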