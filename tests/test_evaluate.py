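import numpy as np
import pytest

from exlwgs import evaluate
from exlwgs.evaluate import (
    assign_haplogroup,
    call_set_sensitivity_fdr,
    dosage_r2,
    genotype_discordance,
    haplogroup_proportions,
    haplogroup_sequence,
    holdout_every_kth,
    mito_consensus,
    mt_reference_sequence,
    synthetic_haplogroup_table,
)


class TestSensitivityFdr:
    def test_perfect_callset(self):
        pos = np.array([1, 2, 3])
        maf = np.array([0.15, 0.25, 0.45])
        df = call_set_sensitivity_fdr(pos, maf, pos, maf)
        overall = df[df["overall"]].iloc[0]
        assert overall["sensitivity"] == 1.0 and overall["fdr"] == 0.0

    def test_toy_counting(self):
        truth = np.array([1, 2, 3])
        called = np.array([2, 3, 4])
        maf = np.full(3, 0.3)
        df = call_set_sensitivity_fdr(called, maf, truth, maf)
        overall = df[df["overall"]].iloc[0]
        assert overall["sensitivity"] == pytest.approx(2 / 3)
        assert overall["fdr"] == pytest.approx(1 / 3)

    def test_empty_callset(self):
        truth = np.array([1, 2])
        df = call_set_sensitivity_fdr(
            np.array([]), np.array([]), truth, np.array([0.2, 0.3])
        )
        overall = df[df["overall"]].iloc[0]
        assert overall["sensitivity"] == 0.0
        assert np.isnan(overall["fdr"])

    def test_empty_truth_bin_nan(self):
        df = call_set_sensitivity_fdr(
            np.array([1]), np.array([0.15]), np.array([1]), np.array([0.15])
        )
        empty = df[(df["bin_low"] == 0.3) & (~df["overall"])].iloc[0]
        assert np.isnan(empty["sensitivity"])


class TestDiscordance:
    def test_perfect(self):
        g = np.ones((4, 5), dtype=np.int8)
        out = genotype_discordance(g, g, depth=np.ones((4, 5)))
        assert out["overall"] == 0.0
        assert (out["strata"]["discordance"].dropna() == 0).all()

    def test_toy_single_error(self):
        truth = np.zeros((2, 3), dtype=np.int8)
        called = truth.copy()
        called[0, 0] = 1
        out = genotype_discordance(called, truth)
        assert out["overall"] == pytest.approx(1 / 6)

    def test_strata_partition_cells(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, (50, 20))
        called = truth.copy()
        depth = rng.poisson(1.6, truth.shape)
        out = genotype_discordance(called, truth, depth=depth)
        assert out["strata"]["n_cells"].sum() == truth.size


class TestHoldout:
    def test_masked_count_and_fraction(self):
        pos = np.arange(1, 1001)
        design = holdout_every_kth(pos, pos, pos, k=20)
        assert len(design.masked_positions) == 50
        assert design.masked_fraction == pytest.approx(0.05)

    def test_small_intersection_no_mask(self):
        pos = np.arange(19)
        design = holdout_every_kth(pos, pos, pos, k=20)
        assert len(design.masked_positions) == 0

    def test_boundary_exactly_k(self):
        pos = np.arange(1, 21)
        design = holdout_every_kth(pos, pos, pos, k=20)
        assert design.masked_positions.tolist() == [20]  # the 20th site

    def test_intersection_is_three_way(self):
        a, b, c = np.arange(100), np.arange(50, 150), np.arange(25, 75)
        design = holdout_every_kth(a, b, c, k=5)
        assert set(design.intersection) == set(range(50, 75))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            holdout_every_kth([1], [1], [1], k=1)

    def test_empty_intersection(self):
        with pytest.raises(ValueError, match="empty"):
            holdout_every_kth([1], [2], [3])


class TestDosageR2:
    def test_perfect(self):
        x = np.array([0, 1, 2, 1])
        assert dosage_r2(x, x) == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # r = 0.5 by hand Pearson computation -> r2 = 0.25
        assert dosage_r2([0, 1, 2, 1], [0, 1, 1, 2]) == pytest.approx(0.25)

    def test_sign_blind(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])
        assert dosage_r2(2 - x, x) == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            dosage_r2([1, 1, 1], [0, 1, 2])


class TestMito:
    def test_consensus_majority(self):
        counts = np.zeros((1, 4), dtype=int)
        counts[0, 3] = 118  # T
        counts[0, 1] = 2    # C
        assert mito_consensus(counts) == "T"

    def test_depth_gate(self):
        counts = np.zeros((1, 4), dtype=int)
        counts[0, 0] = 5
        assert mito_consensus(counts, min_depth=10) == "N"
        counts[0, 0] = 11
        assert mito_consensus(counts, min_depth=10) == "A"

    def test_tie_is_n(self):
        counts = np.zeros((1, 4), dtype=int)
        counts[0, 0] = 10
        counts[0, 2] = 10
        assert mito_consensus(counts) == "N"

    def test_haplogroup_template_match(self):
        table = synthetic_haplogroup_table(mt_length=2000, n_defining=10)
        ref = mt_reference_sequence(2000)
        seq = haplogroup_sequence(ref, table, "M")
        label, score = assign_haplogroup(seq, table)
        assert label == "M" and score == 1.0

    def test_all_n_unassigned(self):
        table = synthetic_haplogroup_table(mt_length=500, n_defining=5)
        label, score = assign_haplogroup("N" * 500, table)
        assert label == "unassigned" and score == 0.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            assign_haplogroup("ACGT", {})

    def test_proportions_layout(self):
        props = haplogroup_proportions(
            ["M", "M", "R", "M"], ["tribal", "tribal", "caste", "caste"]
        )
        assert props.loc["tribal", "M"] == 1.0
        assert props.loc["caste", "M"] == 0.5

    def test_cohort_mito_summary_pure_m_stratum(self):
        """A stratum simulated 100% haplogroup M reports an M proportion of 1."""
        from exlwgs import cohort, reads

        strata = [cohort.StratumSpec("tribal", 6, (1.0,), {"M": 1.0})]
        pops = [cohort.PopulationSpec("P0", 0.015)]
        coh = cohort.assemble_cohort(
            strata=strata, populations=pops, n_sites=20, region_length=2000,
            mt_length=1200, seed=4,
        )
        out = evaluate.mito_cohort_summary(
            coh, reads.DepthModel(), seed=5,
            table=synthetic_haplogroup_table(mt_length=1200),
        )
        assert out["proportions"].loc["tribal", "M"] == 1.0
        assert abs(out["mean_depths"].mean() / 75 -
                   coh.samples["target_coverage"].mean()) < 0.2


class TestPanelComparison:
    def test_matched_beats_diverged_panel(self):
        """Custom (same-population) panels impute better than panels simulated
        at divergence from the target population."""
        from exlwgs import cohort
        from exlwgs.impute import HaplotypePanel

        rng = np.random.default_rng(9)
        m = 600
        anc = rng.uniform(0.1, 0.9, m)
        own = cohort.build_founder_haplotypes(anc, 15, seed=10)
        haps = cohort.sample_mosaic_haplotypes(
            [own], [1.0], 0.005, seed=11, n_haplotypes=60
        )
        truth_g = (haps[0::2] + haps[1::2]).astype(np.int8).T  # (M, N)
        positions = np.arange(1, m + 1)

        far_freqs = cohort.derive_population_frequencies(anc, 0.2, seed=12)
        far = cohort.build_founder_haplotypes(far_freqs, 15, seed=13)
        far_haps = cohort.sample_mosaic_haplotypes(
            [far], [1.0], 0.005, seed=14, n_haplotypes=40
        )
        generic = HaplotypePanel(far_haps, positions)
        labels = np.array(["s"] * truth_g.shape[1])
        out = evaluate.panel_comparison_experiment(
            truth_g, positions, labels, generic, {"s": 8}, seed=15
        )
        row = out.iloc[0]
        assert row["recovered_custom"] == 1.0 and row["recovered_generic"] == 1.0
        assert row["r2_custom"] > row["r2_generic"]

    def test_too_small_stratum_skipped(self):
        from exlwgs.impute import HaplotypePanel

        g = np.zeros((10, 3), dtype=np.int8)
        panel = HaplotypePanel(np.zeros((2, 10), dtype=np.uint8), np.arange(10))
        with pytest.warns(UserWarning, match="skipped"):
            out = evaluate.panel_comparison_experiment(
                g, np.arange(10), np.array(["a"] * 3), panel, {"a": 5}, seed=0
            )
        assert out.empty
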