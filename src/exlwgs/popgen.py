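"""Population-structure battery: F_ST, PCA, LD pruning, admixture EM.

Estimators follow the field-standard definitions: the Weir & Cockerham
(1984) variance-components F_ST with the weighted mean Sum(a)/Sum(a+b+c);
Patterson-normalised PCA (centre by 2p, scale by sqrt(p(1-p))) without
outlier removal; greedy sliding-window r^2 pruning; and maximum-likelihood
admixture proportions under the binomial admixture model
g_il ~ Binomial(2, sum_k q_ik f_kl), fit by EM.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from exlwgs._rng import as_rng
from exlwgs.calling import MISSING

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(genotypes, pop_labels, pair=None):
    """Two-population Weir & Cockerham (1984) F_ST.

    genotypes: (N, M) in {0,1,2,MISSING}; pop_labels: length-N labels;
    pair: the two labels to compare (default: the only two present).

    Returns (components, weighted_mean): components is an (M, 3) array of
    the per-site (a, b, c) variance components (NaN where undefined) and
    weighted_mean = Sum(a) / Sum(a+b+c) over sites with a defined,
    positive-information denominator.  Monomorphic sites contribute
    nothing to the sums.
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(pop_labels)
    if pair is None:
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError("specify `pair` when more than two labels present")
        pair = tuple(uniq)
    masks = [labels == p for p in pair]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("both populations need >= 2 samples")

    r = 2
    n_i = np.empty((2, g.shape[1]))
    p_i = np.empty((2, g.shape[1]))
    h_i = np.empty((2, g.shape[1]))
    for k, mask in enumerate(masks):
        sub = g[mask]
        valid = sub != MISSING
        n_i[k] = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[k] = np.where(valid, sub, 0).sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = np.where(valid & (sub == 1), 1, 0).sum(axis=0) / n_i[k]

    usable = (n_i >= 2).all(axis=0)
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    monomorphic = (p_bar == 0) | (p_bar == 1)
    defined = usable & ~monomorphic
    comp = np.full((g.shape[1], 3), np.nan)
    comp[defined, 0] = a[defined]
    comp[defined, 1] = b[defined]
    comp[defined, 2] = c[defined]
    denom = np.nansum(comp[defined].sum(axis=1))
    if denom == 0:
        warnings.warn("no informative sites for F_ST")
        return comp, float("nan")
    return comp, float(np.nansum(comp[defined, 0]) / denom)


def fst_matrix(genotypes, pop_labels):
    """Pairwise weighted F_ST for all label pairs; returns (labels, matrix)."""
    labels = np.asarray(pop_labels)
    uniq = list(dict.fromkeys(labels))
    k = len(uniq)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, w = weir_cockerham_fst(genotypes, labels, (uniq[i], uniq[j]))
            out[i, j] = out[j, i] = w
    return uniq, out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotype(genotypes, n_components: int = 10):
    """Patterson-normalised PCA of a genotype (or dosage) matrix.

    genotypes: (N, M); missing (MISSING for int matrices, NaN for float)
    entries are mean-imputed per site.  Each site is centred by 2p and
    scaled by sqrt(p(1-p)) with p the observed alternate frequency;
    monomorphic sites are excluded (count logged).  No outlier iteration.

    Returns (coords (N, n_components), variance_fractions (n_components,)):
    coordinates are eigenvectors of the sample covariance scaled by the
    square root of their eigenvalues; fractions are over all positive
    eigenvalues so they sum to 1 across the full spectrum.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        site_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), site_mean[None, :], g)
    p = site_mean / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("pca: excluded %d monomorphic sites", n_dropped)
    g = g[:, poly]
    p = p[poly]
    x = (g - 2 * p[None, :]) / np.sqrt(p * (1 - p))[None, :]
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    n_components = min(n_components, len(eigval))
    coords = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])[None, :]
    total = eigval.sum()
    frac = eigval[:n_components] / total if total > 0 else np.zeros(n_components)
    return coords, frac


def expected_genotype_from_gl(gl, allele_freqs):
    """Posterior-mean dosages E[g | GL, HWE(AF)] for GL-based analyses.

    gl: (M, N, 3) log-likelihoods; allele_freqs: (M,).  Returns an (N, M)
    real dosage matrix (zero-depth cells fall back to the prior mean 2p).
    """
    gl = np.asarray(gl, dtype=float)
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True))
    f = np.asarray(allele_freqs, dtype=float)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    post = lik * prior[:, None, :]
    post /= post.sum(axis=-1, keepdims=True)
    return (post[..., 1] + 2.0 * post[..., 2]).T


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(genotypes, site_i: int, site_j: int) -> float:
    """Squared Pearson correlation of two sites' dosage vectors over
    samples where both are non-missing; NaN if either is constant."""
    g = np.asarray(genotypes, dtype=float)
    x, y = g[:, site_i], g[:, site_j]
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.2,
):
    """Greedy sliding-window LD pruning (PLINK indep-pairwise style).

    Scans windows of ``window`` sites sliding by ``step`` in positional
    order; within a window, for every pair of still-kept sites with
    r^2 strictly greater than the threshold, the later site is dropped.
    Deterministic.  Returns the sorted indices of retained sites.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    m = g.shape[1]
    kept = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step):
        idx = [i for i in range(start, min(start + window, m)) if kept[i]]
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            if not kept[i]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                if not kept[j]:
                    continue
                xi, xj = g[:, i], g[:, j]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() < 2:
                    continue
                x, y = xi[ok], xj[ok]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if r * r > r2_threshold:
                    kept[j] = False
        if start + window >= m:
            break
    return np.flatnonzero(kept)


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

def _admixture_loglik(g, q, f):
    p = np.clip(q @ f, 1e-12, 1 - 1e-12)
    return float(np.sum(g * np.log(p) + (2 - g) * np.log1p(-p)))


def admixture_em(
    genotypes,
    k: int,
    tol: float = 1e-4,
    max_iter: int = 500,
    seed=None,
    n_init: int = 3,
):
    """Admixture proportions by EM on the binomial admixture likelihood.

    genotypes: (N, M) in {0,1,2}; missing cells are not supported here --
    prune and complete the matrix first.  Maximises
    sum_il [g log(sum_k q_ik f_kl) + (2-g) log(sum_k q_ik (1-f_kl))] by
    alternating expectation updates of Q rows (on the simplex) and F
    entries (clipped to [1e-6, 1-1e-6]).  Runs ``n_init`` seeded restarts
    and keeps the best likelihood.

    Returns (Q (N, k), F (k, M), loglik).
    """
    g = np.asarray(genotypes, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n, m = g.shape
    if k == 1:
        f = (g.mean(axis=0) / 2.0)[None, :].clip(1e-6, 1 - 1e-6)
        q = np.ones((n, 1))
        return q, f, _admixture_loglik(g, q, f)

    rng = as_rng(seed)
    best = None
    for _ in range(n_init):
        q = rng.dirichlet(np.ones(k), size=n)
        f = np.clip(
            g.mean(axis=0) / 2.0 + rng.normal(0, 0.05, size=(k, m)), 0.05, 0.95
        )
        ll_prev = -np.inf
        for it in range(max_iter):
            p = np.clip(q @ f, 1e-12, 1 - 1e-12)  # (N, M)
            # responsibilities for alt and ref allele copies
            # a_ilk = q_ik f_kl / p_il ; b_ilk = q_ik (1-f_kl) / (1-p_il)
            alt_w = g / p       # (N, M)
            ref_w = (2 - g) / (1 - p)
            # expected alt/ref copies attributed to component k
            alt_k = np.einsum("nm,nk,km->nk", alt_w, q, f)
            ref_k = np.einsum("nm,nk,km->nk", ref_w, q, 1 - f)
            q_new = alt_k + ref_k
            q_new /= q_new.sum(axis=1, keepdims=True)
            alt_f = np.einsum("nm,nk->km", alt_w, q) * f
            ref_f = np.einsum("nm,nk->km", ref_w, q) * (1 - f)
            f_new = np.clip(alt_f / (alt_f + ref_f), 1e-6, 1 - 1e-6)
            q, f = q_new, f_new
            ll = _admixture_loglik(g, q, f)
            if abs(ll - ll_prev) < tol:
                ll_prev = ll
                break
            ll_prev = ll
        if (q.sum(axis=0) < 1e-6).any():
            warnings.warn("admixture: a component collapsed to zero weight")
        if best is None or ll_prev > best[2]:
            best = (q, f, ll_prev)
    return best
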