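import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exlwgs import calling
from exlwgs.calling import (
    MISSING,
    CallerConfig,
    CallSet,
    call_cohort,
    consensus_merge,
    estimate_allele_frequency_em,
    genotype_likelihoods_from_counts,
    hard_filter_caller,
    maf_filter,
    sample_qc_outliers,
    site_discovery_lrt,
    titv_ratio,
)


def _lik(gl):
    return np.exp(gl)


class TestGenotypeLikelihoods:
    def test_no_data_is_flat(self):
        gl = genotype_likelihoods_from_counts(np.array(0), np.array(0), 0.01)
        assert np.allclose(gl, 0.0)

    @pytest.mark.parametrize(
        "n_ref,n_alt",
        [(3, 0), (1, 1), (0, 3), (5, 2), (0, 0), (10, 10)],
    )
    def test_matches_binomial_pmf_oracle(self, n_ref, n_alt):
        eps = 0.01
        gl = genotype_likelihoods_from_counts(np.array(n_ref), np.array(n_alt), eps)
        n = n_ref + n_alt
        raw = np.array(
            [stats.binom.pmf(n_alt, n, p) for p in (eps, 0.5, 1 - eps)]
        )
        if n == 0:
            raw = np.ones(3)
        assert np.allclose(_lik(gl), raw / raw.max(), rtol=1e-9)

    def test_worked_example_values(self):
        # (3 ref, 0 alt): raw likelihoods 0.970299, 0.125, 1e-6
        gl = genotype_likelihoods_from_counts(np.array(3), np.array(0), 0.01)
        raw = _lik(gl) * 0.970299
        assert np.allclose(raw, [0.970299, 0.125, 1e-6], rtol=1e-6)
        # (1 ref, 1 alt): raw 0.0198, 0.5, 0.0198, symmetric
        gl = genotype_likelihoods_from_counts(np.array(1), np.array(1), 0.01)
        raw = _lik(gl) * 0.5
        assert np.allclose(raw, [0.0198, 0.5, 0.0198], rtol=1e-9)

    def test_ref_alt_symmetry(self, rng):
        n_ref = rng.integers(0, 6, size=50)
        n_alt = rng.integers(0, 6, size=50)
        a = genotype_likelihoods_from_counts(n_ref, n_alt, 0.01)
        b = genotype_likelihoods_from_counts(n_alt, n_ref, 0.01)
        assert np.allclose(a, b[..., ::-1])

    def test_bad_eps(self):
        with pytest.raises(ValueError):
            genotype_likelihoods_from_counts(np.array(1), np.array(1), 0.7)


def _grid_af_oracle(gl, grid_step=1e-4):
    """Independent grid-search maximiser of the HWE-mixture likelihood."""
    lik = np.exp(gl - gl.max(axis=-1, keepdims=True))
    fs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    priors = np.stack([(1 - fs) ** 2, 2 * fs * (1 - fs), fs**2], axis=-1)
    per = np.log(np.einsum("nk,fk->nf", lik, priors) + 1e-300).sum(axis=0)
    return fs[np.argmax(per)]


class TestAlleleFrequencyEM:
    def test_all_hom_ref(self):
        gl = np.log(np.array([[1, 1e-12, 1e-12]] * 4))
        f, _, conv = estimate_allele_frequency_em(gl)
        assert f == pytest.approx(0.0, abs=1e-4)
        assert conv

    def test_all_het(self):
        gl = np.log(np.array([[1e-12, 1.0, 1e-12]] * 2))
        f, post, _ = estimate_allele_frequency_em(gl)
        assert f == pytest.approx(0.5, abs=1e-6)
        assert np.allclose(post[:, 1], 1.0, atol=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(200):
            n = 5
            depth = rng.poisson(1.6, size=n)
            truth = rng.integers(0, 3, size=n)
            p_alt = np.array([0.01, 0.5, 0.99])[truth]
            alt = rng.binomial(depth, p_alt)
            gl = genotype_likelihoods_from_counts(depth - alt, alt, 0.01)
            f, _, _ = estimate_allele_frequency_em(gl, tol=1e-8, max_iter=500)
            assert abs(f - _grid_af_oracle(gl)) < 2e-4


class TestDiscovery:
    def test_zero_depth_not_called(self):
        gl = np.zeros((10, 3))
        lam, called = site_discovery_lrt(gl, CallerConfig())
        assert lam == pytest.approx(0.0, abs=1e-9)
        assert not called

    def test_strong_het_signal_called(self, rng):
        # 50 samples, 10 with clear het pileups at depth 6
        n_ref = np.full(50, 4)
        n_alt = np.zeros(50, dtype=int)
        n_ref[:10] = 3
        n_alt[:10] = 3
        gl = genotype_likelihoods_from_counts(n_ref, n_alt, 0.01)
        lam, called = site_discovery_lrt(gl, CallerConfig())
        assert lam > 20 and called

    def test_threshold_inclusive(self):
        gl = np.zeros((5, 3))
        cfg = CallerConfig(discovery_threshold=0.0 + 1e-300)
        lam, called = site_discovery_lrt(gl, cfg)
        assert called  # lambda == 0 >= s -> called at s ~ 0

    def test_sensitivity_monotone_in_threshold(self, small_cohort, small_gl):
        truth_maf = small_cohort.genotypes().mean(axis=0) / 2.0
        truth_maf = np.minimum(truth_maf, 1 - truth_maf)
        common = truth_maf >= 0.10
        lam, _ = site_discovery_lrt(small_gl, CallerConfig())
        sens = [
            ((lam >= s) & common).sum() / common.sum()
            for s in (0.5, 2.8, 10.0, 50.0)
        ]
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestHardFilter:
    def test_no_alt_reads(self):
        cfg = CallerConfig()
        called = hard_filter_caller(np.full((1, 10), 3), np.zeros((1, 10)), cfg)
        assert not called[0]

    def test_boundary_sample_count(self):
        cfg = CallerConfig(min_alt_samples=2, min_alt_reads=2)
        n_alt = np.zeros((1, 10), dtype=int)
        n_alt[0, :2] = 2  # exactly 2 qualifying samples
        n_ref = np.full((1, 10), 2)
        assert hard_filter_caller(n_ref, n_alt, cfg)[0]
        n_alt[0, 1] = 1  # now only 1 qualifies
        assert not hard_filter_caller(n_ref, n_alt, cfg)[0]

    def test_balanced_site_called(self):
        cfg = CallerConfig(min_alt_reads=1)
        n_ref = np.full((1, 100), 1)
        n_alt = np.full((1, 100), 1)
        assert hard_filter_caller(n_ref, n_alt, cfg)[0]

    def test_pooled_fraction_gate(self):
        # all reads alternate -> pooled fraction 1 > 1 - 3 eps -> rejected
        cfg = CallerConfig()
        n_alt = np.full((1, 50), 3)
        assert not hard_filter_caller(np.zeros((1, 50)), n_alt, cfg)[0]


def _toy_callset(positions, refs=None, alts=None, genotypes=None, n_samples=2):
    m = len(positions)
    refs = refs or ["A"] * m
    alts = alts or ["G"] * m
    sites = pd.DataFrame(
        {
            "position": positions,
            "ref": refs,
            "alt": alts,
            "af": [0.5] * m,
            "stat": [10.0] * m,
            "provenance": ["A"] * m,
        }
    )
    g = np.ones((m, n_samples), dtype=np.int8) if genotypes is None else genotypes
    return CallSet(sites=sites, genotypes=g, dosages=g.astype(float),
                   sample_ids=[f"s{i}" for i in range(n_samples)])


class TestMergeAndFilter:
    def test_consensus_is_intersection(self):
        a = _toy_callset([10, 20])
        b = _toy_callset([20, 30])
        merged = consensus_merge(a, b)
        assert merged.sites["position"].tolist() == [20]
        assert (merged.sites["provenance"] == "consensus").all()

    def test_disjoint_gives_empty(self):
        merged = consensus_merge(_toy_callset([1]), _toy_callset([2]))
        assert merged.n_sites == 0

    def test_genotypes_come_from_first_callset(self):
        ga = np.array([[2, 2]], dtype=np.int8)
        gb = np.array([[0, 0]], dtype=np.int8)
        merged = consensus_merge(
            _toy_callset([5], genotypes=ga), _toy_callset([5], genotypes=gb)
        )
        assert np.array_equal(merged.genotypes, ga)

    def test_allele_mismatch_excluded(self, caplog):
        a = _toy_callset([7], alts=["G"])
        b = _toy_callset([7], alts=["T"])
        merged = consensus_merge(a, b)
        assert merged.n_sites == 0

    def test_consensus_subset_of_inputs(self, small_cohort, small_pileup):
        a, b = call_cohort(
            small_pileup, small_cohort.sites, small_cohort.samples["id"]
        )
        merged = consensus_merge(a, b)
        assert merged.site_keys() <= a.site_keys()
        assert merged.site_keys() <= b.site_keys()

    def test_maf_threshold_inclusive(self):
        # 10 samples: 2 hets -> called MAF exactly 0.10
        g = np.zeros((2, 10), dtype=np.int8)
        g[0, :2] = 1          # MAF 0.10 -> kept
        g[1, 0] = 1           # MAF 0.05 -> dropped
        cs = _toy_callset([1, 2], genotypes=g, n_samples=10)
        kept = maf_filter(cs, 0.10)
        assert kept.sites["position"].tolist() == [1]

    def test_monomorphic_dropped(self):
        g = np.zeros((1, 4), dtype=np.int8)
        assert maf_filter(_toy_callset([1], genotypes=g, n_samples=4)).n_sites == 0


class TestTiTv:
    def test_simple_count(self):
        sites = pd.DataFrame({"ref": ["A", "C", "A"], "alt": ["G", "T", "C"]})
        assert titv_ratio(sites) == pytest.approx(2.0)

    def test_no_transversions_nan(self):
        sites = pd.DataFrame({"ref": ["A"], "alt": ["G"]})
        with pytest.warns(UserWarning):
            assert np.isnan(titv_ratio(sites))

    def test_spectrum_recovery(self):
        from exlwgs.cohort import draw_ancestral_sites

        sites = draw_ancestral_sites(100_000, 10**6, titv_odds=2.09, seed=9)
        assert titv_ratio(sites) == pytest.approx(2.09, abs=0.05)


class TestSampleQc:
    def test_identical_counts_no_flags(self):
        with pytest.warns(UserWarning, match="MAD"):
            flagged, _ = sample_qc_outliers([100, 100, 100, 100])
        assert flagged == []

    def test_extreme_sample_flagged(self):
        counts = [100, 102, 98, 101, 99, 1000]
        flagged, _ = sample_qc_outliers(counts, sample_ids=list("abcdef"))
        assert flagged == ["f"]

    def test_batch_enrichment_reported(self):
        counts = [100, 101, 99, 102, 98, 100, 101, 99, 102, 98] + [10_000] * 5
        batches = ["b1"] * 10 + ["b2"] * 5
        flagged, report = sample_qc_outliers(counts, batch_labels=batches)
        assert len(flagged) == 5
        p_b2 = report.loc[report["batch"] == "b2", "p_value"].iloc[0]
        # all flags in batch 2: Fisher p = 1 / C(15,5)
        assert p_b2 == pytest.approx(1 / 3003, rel=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sample_qc_outliers([1, 2])


def test_threshold_tuning_bounds_fdr(small_cohort, small_gl):
    """The tuning utility picks the smallest s whose training FDR is bounded."""
    truth_maf = small_cohort.genotypes().mean(axis=0) / 2.0
    is_variant = np.minimum(truth_maf, 1 - truth_maf) > 0
    candidates = [0.5, 2.8, 10.0]
    s = calling.tune_discovery_threshold(
        small_gl, is_variant, candidates, max_fdr=0.03
    )
    assert s in candidates
    lam, _ = site_discovery_lrt(small_gl, CallerConfig())
    called = lam >= s
    fdr = (called & ~is_variant).sum() / max(called.sum(), 1)
    assert fdr <= 0.03


def test_high_depth_calls_match_truth(small_cohort):
    """At 30x, called genotypes equal truth at essentially every covered cell."""
    from exlwgs import reads

    g = small_cohort.genotypes()
    pile = reads.simulate_pileups(g, np.full(g.shape[0], 30.0), 0.005, seed=13)
    a, _ = call_cohort(pile, small_cohort.sites, small_cohort.samples["id"])
    lam_order = np.isin(
        small_cohort.sites["position"].to_numpy(), a.sites["position"].to_numpy()
    )
    called = a.genotypes
    truth = g.T[lam_order]
    covered = pile.depth[lam_order] > 0
    assert (called[covered] == truth[covered]).mean() > 0.999
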