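"""Genotype likelihoods, joint calling and the two-caller consensus.

The calling stack mirrors a population-scale low-coverage pipeline:

* per-cell binomial genotype likelihoods from ref/alt read counts;
* per-site allele-frequency EM under Hardy-Weinberg across all samples
  (joint calling: single-sample evidence is weak at ~1.6x, the
  population carries the information);
* caller A: a polymorphism likelihood-ratio test with inclusive
  threshold ``s`` (the variance-ratio-statistic analog used by
  GL-based callers; default s = 2.8);
* caller B: a read-count hard-filter caller (a deliberately independent
  second discovery route);
* consensus: intersection of the two site lists, genotypes taken from
  caller A;
* MAF >= 10% final filtering, Ti/Tv accounting, and robust per-sample
  SNV-count QC.

All thresholds are inclusive (>=).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for no-call cells


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    """Discovery thresholds.

    discovery_threshold: LRT threshold s (inclusive) for caller A.
    min_alt_reads / min_alt_samples: a site passes caller B iff at least
    ``min_alt_samples`` samples carry >= ``min_alt_reads`` alternate reads
    and the pooled alternate-read fraction lies in [3*eps, 1 - 3*eps].
    """

    discovery_threshold: float = 2.8
    error_rate: float = 0.005
    min_alt_samples: int = 2
    min_alt_reads: int = 2

    def __post_init__(self):
        if self.discovery_threshold <= 0:
            raise ValueError("discovery threshold s must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


@dataclasses.dataclass
class CallSet:
    """Discovered sites plus per-sample genotypes and dosages.

    sites: DataFrame with columns position, ref, alt, af, stat, provenance.
    genotypes: (n_sites, n_samples) int8 in {0,1,2,MISSING}.
    dosages: (n_sites, n_samples) float in [0,2].
    sample_ids: list of sample identifiers (column order).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    dosages: np.ndarray
    sample_ids: list

    def __post_init__(self):
        if len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("sites/genotypes row mismatch")
        if self.genotypes.shape != self.dosages.shape:
            raise ValueError("genotype/dosage shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> set:
        return set(
            zip(self.sites["position"], self.sites["ref"], self.sites["alt"])
        )

    def called_maf(self) -> np.ndarray:
        """Minor allele frequency from called (non-missing) genotypes."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-missing rows yield masked means
            p = g.mean(axis=1).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------

def genotype_likelihoods_from_counts(
    n_ref: np.ndarray, n_alt: np.ndarray, error_rate: float
) -> np.ndarray:
    """Binomial genotype log-likelihoods.

    For a cell with ``n = n_ref + n_alt`` reads of which ``n_alt`` carry the
    alternate allele, L_g = C(n, n_alt) p_g^n_alt (1-p_g)^(n-n_alt) with
    p_0 = eps, p_1 = 1/2, p_2 = 1 - eps.  Returned in natural-log space,
    normalised so the per-cell maximum is 0 (i.e. max likelihood 1);
    zero-depth cells get (0, 0, 0).

    Accepts scalars or arrays; output shape = input shape + (3,).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    if (n_ref < 0).any() or (n_alt < 0).any():
        raise ValueError("counts must be nonnegative")
    n = n_ref + n_alt
    log_choose = gammaln(n + 1) - gammaln(n_alt + 1) - gammaln(n_ref + 1)
    p = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            log_choose[..., None]
            + n_alt[..., None] * np.log(p)
            + n_ref[..., None] * np.log1p(-p)
        )
    # 0 * log(0) -> 0 for eps = 0 edge
    ll = np.where(np.isnan(ll), -np.inf, ll)
    ll = np.where((n[..., None] == 0), 0.0, ll)
    return ll - ll.max(axis=-1, keepdims=True)


def _hwe_priors(f):
    """Genotype priors under Hardy-Weinberg at alt frequency f (stacked last axis)."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def estimate_allele_frequency_em(
    gl: np.ndarray, tol: float = 1e-6, max_iter: int = 100
):
    """Per-site allele-frequency EM under Hardy-Weinberg.

    gl: (..., N, 3) genotype log-likelihoods for N samples, possibly for
    many sites at once (leading axes).  The E-step computes genotype
    posteriors proportional to L_g * HWE_g(f); the M-step sets
    f = sum E[g] / 2N.  Iterates until |df| < tol everywhere or max_iter.

    Returns (f, posteriors, converged): f has the leading shape, posteriors
    the full input shape, converged a boolean array (non-convergence is
    flagged, not raised).
    """
    gl = np.asarray(gl, dtype=float)
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True))
    n = gl.shape[-2]
    if n < 1:
        raise ValueError("need at least one sample")
    f = np.full(gl.shape[:-2], 0.2)
    converged = np.zeros(gl.shape[:-2], dtype=bool)
    post = None
    for _ in range(max_iter):
        prior = _hwe_priors(f)[..., None, :]
        post = lik * prior
        post /= post.sum(axis=-1, keepdims=True)
        e_g = post[..., 1] + 2.0 * post[..., 2]
        f_new = e_g.sum(axis=-1) / (2.0 * n)
        delta = np.abs(f_new - f)
        f = f_new
        converged = delta < tol
        if converged.all():
            break
    prior = _hwe_priors(f)[..., None, :]
    post = lik * prior
    post /= post.sum(axis=-1, keepdims=True)
    return f, post, converged


def _hwe_loglik(lik: np.ndarray, f) -> np.ndarray:
    """Population log-likelihood sum_i log sum_g L_ig HWE_g(f)."""
    prior = _hwe_priors(f)[..., None, :]
    per_sample = (lik * prior).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return np.log(per_sample).sum(axis=-1)


def site_discovery_lrt(gl: np.ndarray, config: CallerConfig, f_hat=None):
    """Polymorphism likelihood-ratio statistic and call decision.

    Lambda = log L(f_hat) - max(log L(f=0), log L(f=1)) under the
    HWE-mixture likelihood; a site is called variant iff Lambda >=
    ``config.discovery_threshold`` (inclusive).  Vectorised over leading
    site axes; returns (Lambda, is_variant).  ``f_hat`` may be supplied to
    reuse an existing EM fit.
    """
    gl = np.asarray(gl, dtype=float)
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True))
    if f_hat is None:
        f_hat, _, _ = estimate_allele_frequency_em(gl)
    f_hat = np.asarray(f_hat, dtype=float)
    ll_hat = _hwe_loglik(lik, f_hat)
    ll_mono = np.maximum(
        _hwe_loglik(lik, np.zeros_like(f_hat)),
        _hwe_loglik(lik, np.ones_like(f_hat)),
    )
    lam = ll_hat - ll_mono
    # EM initialisation cannot make the ratio negative beyond roundoff
    lam = np.maximum(lam, 0.0)
    return lam, lam >= config.discovery_threshold


def hard_filter_caller(
    n_ref: np.ndarray, n_alt: np.ndarray, config: CallerConfig
) -> np.ndarray:
    """Read-count hard-filter site discovery (caller B).

    A site is variant iff (# samples with >= min_alt_reads alternate reads)
    >= min_alt_samples, and the pooled alternate-read fraction lies in
    [3 eps, 1 - 3 eps].  Vectorised over sites: inputs (M, N).
    """
    n_ref = np.atleast_2d(np.asarray(n_ref))
    n_alt = np.atleast_2d(np.asarray(n_alt))
    eps = config.error_rate
    qualifying = (n_alt >= config.min_alt_reads).sum(axis=-1)
    total = (n_ref + n_alt).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        pooled = np.where(total > 0, n_alt.sum(axis=-1) / np.maximum(total, 1), 0.0)
    return (
        (qualifying >= config.min_alt_samples)
        & (pooled >= 3.0 * eps)
        & (pooled <= 1.0 - 3.0 * eps)
    )


# ---------------------------------------------------------------------------
# whole-cohort calling
# ---------------------------------------------------------------------------

def call_cohort(
    pileup,
    site_table: pd.DataFrame,
    sample_ids,
    config: CallerConfig | None = None,
) -> tuple:
    """Run both callers over a pileup and return (callset_A, callset_B).

    ``site_table`` must carry position/ref/alt for every pileup row.
    Caller A (LRT) supplies genotypes (posterior argmax at f_hat), dosages
    (posterior mean) and the discovery statistic; zero-depth cells are
    emitted as MISSING genotypes with prior-mean dosages.  Caller B is a
    site list only; its genotype/dosage matrices are filled from the same
    likelihood layer for interface uniformity.
    """
    config = config or CallerConfig()
    gl = genotype_likelihoods_from_counts(
        pileup.n_ref, pileup.n_alt, config.error_rate
    )
    f_hat, post, _ = estimate_allele_frequency_em(gl, tol=1e-5, max_iter=60)
    lam, called_a = site_discovery_lrt(gl, config, f_hat=f_hat)
    called_b = hard_filter_caller(pileup.n_ref, pileup.n_alt, config)

    geno = post.argmax(axis=-1).astype(np.int8)
    dosage = post[..., 1] + 2.0 * post[..., 2]
    zero_depth = pileup.depth == 0
    geno[zero_depth] = MISSING

    def _subset(mask, stat, provenance):
        sites = site_table.loc[mask, ["position", "ref", "alt"]].copy()
        sites["af"] = f_hat[mask]
        sites["stat"] = stat[mask]
        sites["provenance"] = provenance
        return CallSet(
            sites=sites.reset_index(drop=True),
            genotypes=geno[mask],
            dosages=dosage[mask],
            sample_ids=list(sample_ids),
        )

    return _subset(called_a, lam, "A"), _subset(called_b, lam, "B")


def consensus_merge(callset_a: CallSet, callset_b: CallSet) -> CallSet:
    """Consensus of two call sets: the (position, ref, alt) intersection,
    with genotypes/dosages taken from callset_a (the likelihood caller).

    Sites sharing a position but disagreeing on alleles are excluded and
    logged."""
    keys_b = callset_b.site_keys()
    pos_b = set(callset_b.sites["position"])
    keep = []
    for i, row in callset_a.sites.iterrows():
        key = (row["position"], row["ref"], row["alt"])
        if key in keys_b:
            keep.append(i)
        elif row["position"] in pos_b:
            logger.warning(
                "allele mismatch at position %s: excluded from consensus",
                row["position"],
            )
    idx = np.array(keep, dtype=int)
    sites = callset_a.sites.iloc[idx].copy().reset_index(drop=True)
    sites["provenance"] = "consensus"
    return CallSet(
        sites=sites,
        genotypes=callset_a.genotypes[idx],
        dosages=callset_a.dosages[idx],
        sample_ids=callset_a.sample_ids,
    )


def maf_filter(callset: CallSet, threshold: float = 0.10) -> CallSet:
    """Keep sites whose called-genotype MAF is >= threshold (inclusive)."""
    maf = callset.called_maf()
    keep = np.nan_to_num(maf, nan=-1.0) >= threshold
    return CallSet(
        sites=callset.sites.loc[keep].reset_index(drop=True),
        genotypes=callset.genotypes[keep],
        dosages=callset.dosages[keep],
        sample_ids=callset.sample_ids,
    )


def titv_ratio(sites: pd.DataFrame | CallSet) -> float:
    """Transition/transversion count ratio of a site table or call set.

    Classes are resolved from (ref, alt).  Returns NaN with a warning when
    there are no transversions."""
    if isinstance(sites, CallSet):
        sites = sites.sites
    from exlwgs.cohort import mutation_class

    classes = [
        mutation_class(r, a) for r, a in zip(sites["ref"], sites["alt"])
    ]
    n_ti = sum(c == "transition" for c in classes)
    n_tv = len(classes) - n_ti
    if n_tv == 0:
        warnings.warn("no transversions in call set; Ti/Tv undefined")
        return float("nan")
    return n_ti / n_tv


def sample_qc_outliers(
    snv_counts,
    sample_ids=None,
    batch_labels=None,
    z_threshold: float = 3.0,
):
    """Flag samples with outlying SNV counts by robust z-score.

    Uses median/MAD (MAD scaled by 1.4826); MAD = 0 falls back to mean/sd
    with a warning.  With batch labels, reports Fisher-exact enrichment of
    flags in each batch.  Returns (flagged sample ids, batch report | None).
    """
    counts = np.asarray(snv_counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 samples for outlier QC")
    if sample_ids is None:
        sample_ids = list(range(counts.size))
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    if mad == 0:
        warnings.warn("MAD is zero; falling back to mean/sd z-scores")
        sd = counts.std()
        z = np.zeros_like(counts) if sd == 0 else (counts - counts.mean()) / sd
    else:
        z = (counts - med) / (1.4826 * mad)
    flagged_mask = z > z_threshold
    flagged = [sid for sid, fl in zip(sample_ids, flagged_mask) if fl]

    batch_report = None
    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)
        rows = []
        for batch in np.unique(batch_labels):
            in_b = batch_labels == batch
            table = [
                [int((flagged_mask & in_b).sum()), int((flagged_mask & ~in_b).sum())],
                [int((~flagged_mask & in_b).sum()), int((~flagged_mask & ~in_b).sum())],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            rows.append({"batch": batch, "n_flagged": table[0][0], "p_value": p})
        batch_report = pd.DataFrame(rows)
    return flagged, batch_report


def tune_discovery_threshold(
    gl: np.ndarray,
    truth_is_variant: np.ndarray,
    candidate_s,
    max_fdr: float = 0.03,
    config: CallerConfig | None = None,
) -> float:
    """Choose the smallest threshold s whose FDR on a training replicate is
    bounded by ``max_fdr`` (the tuning procedure behind the default s)."""
    config = config or CallerConfig()
    lam, _ = site_discovery_lrt(gl, config)
    truth = np.asarray(truth_is_variant, dtype=bool)
    for s in sorted(candidate_s):
        called = lam >= s
        if called.sum() == 0:
            continue
        fdr = (called & ~truth).sum() / called.sum()
        if fdr <= max_fdr:
            return float(s)
    return float(max(candidate_s))
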