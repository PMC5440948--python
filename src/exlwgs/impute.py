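"""Li-Stephens haplotype-copying imputation.

A query haplotype is modelled as an imperfect mosaic of a panel of H
reference haplotypes: a hidden copying template follows a Markov chain
that stays put with probability 1 - switch_prob and otherwise jumps to a
uniformly chosen panel haplotype; the emitted allele matches the
template with probability 1 - mismatch_prob.  Forward-backward posteriors
over templates give expected (dosage-scale) alleles at every site,
including sites with no observation.

Two consumers:

* ``impute_masked_sites`` -- reference-panel imputation of masked
  genotypes (the holdout-benchmark mode), with diploid phasing by
  iterated haploid conditioning;
* ``refine_cohort_genotypes`` -- within-cohort genotype refinement that
  combines each sample's copying posterior (panel = all other samples'
  current haplotypes) with its genotype likelihoods, filling every cell
  including zero-coverage ones.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from numba import njit

from exlwgs._rng import as_rng
from exlwgs.calling import MISSING, estimate_allele_frequency_em

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HmmParams:
    """Copying-model parameters: per-interval template switch probability
    and per-site emission mismatch probability."""

    switch_prob: float = 0.01
    mismatch_prob: float = 0.005

    def __post_init__(self):
        if not 0.0 < self.switch_prob < 1.0:
            raise ValueError("switch_prob must lie in (0, 1)")
        if not 0.0 < self.mismatch_prob < 1.0:
            raise ValueError("mismatch_prob must lie in (0, 1)")


@dataclasses.dataclass
class HaplotypePanel:
    """Reference panel: (H, M) 0/1 haplotype matrix + site positions."""

    haplotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 1:
            raise ValueError("panel must be a nonempty (H, M) matrix")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("panel width != number of positions")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


# ---------------------------------------------------------------------------
# forward-backward core
# ---------------------------------------------------------------------------

def _emissions(panel_t, obs_col, theta, mask=None):
    """(Q, H) emission probabilities at one site; missing obs (-1) emit 1,
    ``mask`` (0/1 float, Q x H) zeroes forbidden templates."""
    e = theta + (1.0 - 2.0 * theta) * (obs_col[:, None] == panel_t[None, :])
    e[obs_col < 0] = 1.0
    if mask is not None:
        e *= mask
    return e


def _forward_backward_block(panel, obs, params, exclude=None):
    """Scaled forward-backward for a block of queries against one panel.

    panel: (H, M) 0/1; obs: (Q, M) int with -1 for missing; exclude:
    optional (Q, H) boolean mask of forbidden templates (their emission is
    zeroed, e.g. a sample's own haplotypes during leave-one-out refinement).

    Returns (expected_alleles (Q, M) float, gamma_last) where gamma at each
    site is the normalised posterior over templates; only the expected
    alleles are stored for all sites to bound memory.
    """
    h, m = panel.shape
    q = obs.shape[0]
    s = params.switch_prob
    theta = params.mismatch_prob
    panel_t = np.ascontiguousarray(panel.T).astype(np.float32)  # (M, H)
    obs = np.ascontiguousarray(obs)
    mask = None
    if exclude is not None:
        mask = (~exclude).astype(np.float32)
    alphas = np.empty((m, q, h), dtype=np.float32)

    a = _emissions(panel_t[0], obs[:, 0], theta, mask) / h
    a /= a.sum(axis=1, keepdims=True)
    alphas[0] = a
    for j in range(1, m):
        e = _emissions(panel_t[j], obs[:, j], theta, mask)
        a = ((1.0 - s) * a + (s / h) * a.sum(axis=1, keepdims=True)) * e
        a /= a.sum(axis=1, keepdims=True)
        alphas[j] = a

    expected = np.empty((q, m), dtype=np.float64)
    b = np.ones((q, h), dtype=np.float32)
    gamma = alphas[m - 1].astype(np.float64)
    gamma /= gamma.sum(axis=1, keepdims=True)
    expected[:, m - 1] = gamma @ panel_t[m - 1].astype(np.float64)
    posteriors_last = gamma
    for j in range(m - 2, -1, -1):
        eb = _emissions(panel_t[j + 1], obs[:, j + 1], theta, mask)
        eb *= b
        b = (1.0 - s) * eb + (s / h) * eb.sum(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)
        gamma = (alphas[j] * b).astype(np.float64)
        gamma /= gamma.sum(axis=1, keepdims=True)
        expected[:, j] = gamma @ panel_t[j].astype(np.float64)
    return expected, posteriors_last


def _batched_expected_alleles(panel, obs, params, exclude=None, block=256):
    """Expected alleles for many queries, chunked to bound the stored
    forward pass at roughly block * M * H float32."""
    q = obs.shape[0]
    out = np.empty(obs.shape, dtype=np.float64)
    for lo in range(0, q, block):
        hi = min(lo + block, q)
        excl = exclude[lo:hi] if exclude is not None else None
        out[lo:hi], _ = _forward_backward_block(panel, obs[lo:hi], params, excl)
    return out


def li_stephens_posteriors(observed, panel: HaplotypePanel, params: HmmParams):
    """Copying posteriors and expected alleles for one query haplotype.

    ``observed`` is a length-M vector over {0, 1, -1 (missing)}.  Returns
    (posteriors (M, H), dosage (M,)): posteriors are the per-site template
    distribution, dosage the posterior expected allele.
    """
    obs = np.asarray(observed, dtype=np.int8)[None, :]
    if obs.shape[1] != panel.haplotypes.shape[1]:
        raise ValueError("observation length != panel width")
    h, m = panel.haplotypes.shape
    # small-scale path that also returns full posteriors
    s, theta = params.switch_prob, params.mismatch_prob
    alphas = np.empty((m, h))
    a = _emissions(panel.haplotypes[:, 0], obs[:, 0], theta)[0] / h
    a /= a.sum()
    alphas[0] = a
    for j in range(1, m):
        e = _emissions(panel.haplotypes[:, j], obs[:, j], theta)[0]
        a = ((1.0 - s) * a + (s / h) * a.sum()) * e
        a /= a.sum()
        alphas[j] = a
    gammas = np.empty((m, h))
    b = np.ones(h)
    gammas[m - 1] = alphas[m - 1] / alphas[m - 1].sum()
    for j in range(m - 2, -1, -1):
        e = _emissions(panel.haplotypes[:, j + 1], obs[:, j + 1], theta)[0]
        eb = e * b
        b = (1.0 - s) * eb + (s / h) * eb.sum()
        b /= b.sum()
        g = alphas[j] * b
        gammas[j] = g / g.sum()
    dosage = np.einsum("mh,hm->m", gammas, panel.haplotypes.astype(float))
    return gammas, dosage


def _extrinsic_allele_prob(posterior_p1, obs, theta):
    """Remove a site's own observation from its copying posterior.

    The forward-backward posterior P(allele = 1) at a site includes that
    site's emission, so it echoes the current observation; for re-phasing
    and for combining with genotype likelihoods we need the leave-site-out
    (extrinsic) probability.  Since gamma_h is proportional to
    extrinsic_h * emission_h, dividing the aggregated allele posterior by
    the emission factor recovers it:

    obs == 1:  ext proportional to (p/(1-theta), (1-p)/theta)
    obs == 0:  ext proportional to (p/theta, (1-p)/(1-theta))
    missing:   the posterior is already extrinsic.
    """
    p = np.clip(posterior_p1, 1e-12, 1.0 - 1e-12)
    w1 = np.where(obs == 1, p / (1.0 - theta), np.where(obs == 0, p / theta, p))
    w0 = np.where(
        obs == 1,
        (1.0 - p) / theta,
        np.where(obs == 0, (1.0 - p) / (1.0 - theta), 1.0 - p),
    )
    return w1 / (w1 + w0)


# ---------------------------------------------------------------------------
# diploid phasing / panel imputation
# ---------------------------------------------------------------------------

def _phase_and_impute(
    genotypes, panel, params, n_rounds=5, seed=None
):
    """Iterated conditional phasing of diploid targets against a panel.

    genotypes: (T, M) in {0,1,2,MISSING}; masked/missing cells are
    imputed.  Each round runs the haploid copying model for both chains
    and re-phases heterozygous sites by the chains' relative posterior
    support.  Returns per-chain expected alleles (e1, e2), each (T, M).
    """
    rng = as_rng(seed)
    g = np.asarray(genotypes)
    t, m = g.shape
    hom_ref = g == 0
    het = g == 1
    hom_alt = g == 2
    miss = ~(hom_ref | het | hom_alt)

    # random initial phase at heterozygous sites
    flip = rng.random((t, m)) < 0.5
    hap1 = np.where(hom_alt, 1, 0).astype(np.int8)
    hap2 = hap1.copy()
    hap1[het] = flip[het]
    hap2[het] = ~flip[het]
    obs1 = np.where(miss, -1, hap1).astype(np.int8)
    obs2 = np.where(miss, -1, hap2).astype(np.int8)

    theta = params.mismatch_prob
    e1 = e2 = None
    for _ in range(n_rounds):
        e1 = _batched_expected_alleles(panel, obs1, params)
        e2 = _batched_expected_alleles(panel, obs2, params)
        # re-phase hets on extrinsic support: allele 1 goes to the chain
        # whose flanking haplotype context favours it more
        ext1 = _extrinsic_allele_prob(e1, obs1, theta)
        ext2 = _extrinsic_allele_prob(e2, obs2, theta)
        assign1 = ext1 * (1.0 - ext2) >= (1.0 - ext1) * ext2
        hap1 = np.where(het, assign1, hap1).astype(np.int8)
        hap2 = np.where(het, ~assign1, hap2).astype(np.int8)
        obs1 = np.where(miss, -1, hap1).astype(np.int8)
        obs2 = np.where(miss, -1, hap2).astype(np.int8)
    return e1, e2


def impute_masked_sites(
    genotypes,
    masked_index,
    panel: HaplotypePanel,
    params: HmmParams | None = None,
    n_rounds: int = 5,
    seed=None,
) -> np.ndarray:
    """Impute masked genotype cells from a reference panel.

    genotypes: (T, M) target genotypes over the panel's site list, in
    {0,1,2,MISSING}.  ``masked_index`` gives the site columns to treat as
    missing (their observed values are ignored).  Returns a (T, n_masked)
    dosage matrix in [0, 2] at the masked columns.
    """
    params = params or HmmParams()
    g = np.asarray(genotypes).astype(np.int8)
    masked_index = np.asarray(masked_index, dtype=int)
    if masked_index.size and (
        masked_index.min() < 0 or masked_index.max() >= g.shape[1]
    ):
        bad = masked_index[(masked_index < 0) | (masked_index >= g.shape[1])]
        raise ValueError(f"masked site indices outside panel: {bad.tolist()}")
    if masked_index.size == 0:
        return np.empty((g.shape[0], 0))
    g[:, masked_index] = MISSING
    e1, e2 = _phase_and_impute(
        g, panel.haplotypes, params, n_rounds=n_rounds, seed=seed
    )
    dosage = e1 + e2
    return np.clip(dosage[:, masked_index], 0.0, 2.0)


# ---------------------------------------------------------------------------
# within-cohort refinement
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _fb_soft_kernel(T, E0, E1, s, mask, ext_out, num, den, accumulate):  # pragma: no cover
    """Fused forward-backward over template states with soft emissions.

    T: (K, M) template allele-1 probabilities (hard panel rows or learned
    cluster haplotypes); E0/E1: (N, M) per-sample emission likelihoods for
    chain allele 0/1 (genotype likelihoods integrated over the partner
    chain); mask: (N, K) 0/1 template admissibility.  Writes the extrinsic
    (leave-site-out) allele-1 probability into ext_out and, when
    ``accumulate``, adds cluster-allele expectations into num/den for the
    EM update of T.  O(M*K) memory per sample.
    """
    K, M = T.shape
    N = E0.shape[0]
    alphas = np.empty((M, K), dtype=np.float32)
    a = np.empty(K, dtype=np.float32)
    b = np.empty(K, dtype=np.float32)
    work = np.empty(K, dtype=np.float32)
    for n in range(N):
        for j in range(M):
            d = E1[n, j] - E0[n, j]
            tot = np.float32(0.0)
            if j == 0:
                for k in range(K):
                    ek = (E0[n, j] + d * T[k, j]) * mask[n, k]
                    a[k] = ek
                    tot += ek
            else:
                asum = np.float32(0.0)
                for k in range(K):
                    asum += a[k]
                for k in range(K):
                    ek = (E0[n, j] + d * T[k, j]) * mask[n, k]
                    av = ((1.0 - s) * a[k] + (s / K) * asum) * ek
                    a[k] = av
                    tot += av
            inv = 1.0 / tot
            for k in range(K):
                a[k] *= inv
                alphas[j, k] = a[k]
        for k in range(K):
            b[k] = 1.0
        for j in range(M - 1, -1, -1):
            if j < M - 1:
                d = E1[n, j + 1] - E0[n, j + 1]
                ebsum = np.float32(0.0)
                for k in range(K):
                    ek = (E0[n, j + 1] + d * T[k, j + 1]) * mask[n, k]
                    work[k] = ek * b[k]
                    ebsum += work[k]
                tot = np.float32(0.0)
                for k in range(K):
                    bv = (1.0 - s) * work[k] + (s / K) * ebsum
                    b[k] = bv
                    tot += bv
                inv = 1.0 / tot
                for k in range(K):
                    b[k] *= inv
            d = E1[n, j] - E0[n, j]
            gtot = np.float32(0.0)
            for k in range(K):
                work[k] = alphas[j, k] * b[k]
                gtot += work[k]
            etot = np.float32(0.0)
            ex1 = np.float32(0.0)
            for k in range(K):
                ek = (E0[n, j] + d * T[k, j]) * mask[n, k]
                ge = work[k] / max(ek, np.float32(1e-30))
                work[k] = ge
                etot += ge
            for k in range(K):
                ex1 += (work[k] / etot) * T[k, j]
            ext_out[n, j] = ex1
            if accumulate:
                ginv = 1.0 / gtot
                for k in range(K):
                    g = alphas[j, k] * b[k] * ginv
                    w1 = T[k, j] * E1[n, j]
                    w0 = (1.0 - T[k, j]) * E0[n, j]
                    num[k, j] += g * (w1 / max(w1 + w0, 1e-30))
                    den[k, j] += g


def _chain_emissions(lik, other_ext):
    """Per-chain allele emissions: genotype likelihoods integrated over the
    partner chain's current allele distribution."""
    e0 = (1.0 - other_ext) * lik[..., 0] + other_ext * lik[..., 1]
    e1 = (1.0 - other_ext) * lik[..., 1] + other_ext * lik[..., 2]
    return e0.astype(np.float32), e1.astype(np.float32)


def _run_chain(T, lik, other_ext, s, mask=None, num=None, den=None):
    """One soft-emission FB sweep for all samples; returns extrinsic allele
    probabilities (N, M)."""
    e0, e1 = _chain_emissions(lik, other_ext)
    n, m = e0.shape
    k = T.shape[0]
    if mask is None:
        mask = np.ones((n, k), dtype=np.float32)
    accumulate = num is not None
    if not accumulate:
        num = np.zeros((1, 1))
        den = np.zeros((1, 1))
    ext = np.empty((n, m), dtype=np.float32)
    _fb_soft_kernel(
        np.ascontiguousarray(T, dtype=np.float32),
        e0, e1, np.float32(s), mask, ext, num, den, accumulate,
    )
    return ext.astype(np.float64)


def _genotype_posterior(ext1, ext2, lik):
    """Copying-prior x GL genotype posterior, (N, M, 3)."""
    prior = np.stack(
        [
            (1 - ext1) * (1 - ext2),
            ext1 * (1 - ext2) + (1 - ext1) * ext2,
            ext1 * ext2,
        ],
        axis=-1,
    )
    post = prior * lik
    post /= post.sum(axis=-1, keepdims=True)
    return post


def _haps_from_posterior(post, ext1, ext2):
    """Hard genotypes + phased haplotypes from a genotype posterior."""
    geno = post.argmax(axis=-1).astype(np.int8)
    het = geno == 1
    assign1 = ext1 * (1.0 - ext2) >= (1.0 - ext1) * ext2
    hap1 = np.where(geno == 2, 1, 0).astype(np.int8)
    hap2 = hap1.copy()
    hap1[het] = assign1[het]
    hap2[het] = ~assign1[het]
    return geno, hap1, hap2


def refine_cohort_genotypes(
    gl: np.ndarray,
    params: HmmParams | None = None,
    n_iter: int = 10,
    seed=None,
    n_clusters: int = 30,
    n_bootstrap: int = 40,
    max_panel: int | None = 200,
):
    """LD-based genotype refinement from genotype likelihoods.

    gl: (M sites, N samples, 3) log-likelihoods.  Two phases:

    1. *Cluster bootstrap* (``n_bootstrap`` sweeps): a haplotype-cluster
       EM learns ``n_clusters`` cluster haplotypes (per-site allele
       frequencies, fastPHASE-style) directly from the GLs.  Each sample
       is modelled as two copying chains over the clusters; a chain's
       emission integrates the genotype likelihood over the partner
       chain's current allele distribution, so no hard genotype or phase
       assignment is ever conditioned on.
    2. *Panel refinement* (``n_iter`` sweeps): the classic within-cohort
       loop -- each sample's chains copy from the current phased
       haplotypes of the other samples (own haplotypes excluded;
       ``max_panel`` caps the panel by seeded subsampling per sweep), with
       the same soft emissions.

    Both phases track the leave-site-out (extrinsic) copying probability
    of each chain; the emitted genotype posterior is extrinsic prior x GL,
    renormalised, so every cell -- including zero-coverage ones -- gets a
    genotype and dosage.

    Returns (genotypes (M, N) int8, dosages (M, N) float).
    """
    params = params or HmmParams()
    rng = as_rng(seed)
    gl = np.asarray(gl, dtype=float)
    m, n, _ = gl.shape
    if n < 2:
        raise ValueError("refinement needs at least 2 samples")
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True)).transpose(1, 0, 2)  # (N, M, 3)
    lik = np.ascontiguousarray(lik, dtype=np.float32)
    s = params.switch_prob
    theta_floor = params.mismatch_prob

    # init from GL x HWE posteriors (allele-frequency EM across samples)
    _, post0, _ = estimate_allele_frequency_em(gl, tol=1e-5, max_iter=60)
    post0 = post0.transpose(1, 0, 2)
    dosage0 = post0[..., 1] + 2.0 * post0[..., 2]
    ext1 = dosage0 / 2.0
    ext2 = ext1.copy()

    # phase 1: haplotype-cluster EM bootstrap
    k = int(min(n_clusters, 2 * n))
    picks = rng.choice(n, size=k, replace=k > n)
    theta = np.clip(
        dosage0[picks] / 2.0 + rng.normal(0.0, 0.05, size=(k, m)), 0.02, 0.98
    )
    for it in range(n_bootstrap):
        num = np.zeros((k, m))
        den = np.zeros((k, m))
        ext1 = _run_chain(theta, lik, ext2, s, num=num, den=den)
        ext2 = _run_chain(theta, lik, ext1, s, num=num, den=den)
        theta = np.clip(num / np.maximum(den, 1e-12), 1e-4, 1.0 - 1e-4)
    post = _genotype_posterior(ext1, ext2, lik)
    geno, hap1, hap2 = _haps_from_posterior(post, ext1, ext2)
    logger.debug("bootstrap done: het fraction %.4f", (geno == 1).mean())

    # phase 2: leave-one-out panel refinement
    for it in range(n_iter):
        panel = np.empty((2 * n, m), dtype=np.float32)
        panel[0::2] = hap1
        panel[1::2] = hap2
        if max_panel is not None and 2 * n > max_panel:
            cols = np.sort(rng.choice(2 * n, size=max_panel, replace=False))
        else:
            cols = np.arange(2 * n)
        owner = cols // 2
        mask = (owner[None, :] != np.arange(n)[:, None]).astype(np.float32)
        t_panel = np.clip(panel[cols], theta_floor, 1.0 - theta_floor)
        ext1 = _run_chain(t_panel, lik, ext2, s, mask=mask)
        ext2 = _run_chain(t_panel, lik, ext1, s, mask=mask)
        post = _genotype_posterior(ext1, ext2, lik)
        geno, hap1, hap2 = _haps_from_posterior(post, ext1, ext2)
        logger.debug(
            "refinement sweep %d: het fraction %.4f", it, (geno == 1).mean()
        )

    dosage = post[..., 1] + 2.0 * post[..., 2]
    return geno.T, np.clip(dosage.T, 0.0, 2.0)
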