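"""Evaluation battery for low-coverage calling and imputation.

Scores a call set against simulated truth (sensitivity/FDR by MAF bin,
genotype discordance strata including zero-coverage heterozygotes), runs
the every-k-th-site imputation holdout with dosage R^2, compares a
population-matched ("custom") reference panel against a diverged
("generic") one, and summarises the mitochondrial contig (majority-rule
consensus, haplogroup typing, per-population lineage proportions).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from exlwgs._rng import as_rng, derive_rng
from exlwgs.calling import MISSING
from exlwgs.impute import HaplotypePanel, HmmParams, impute_masked_sites
from exlwgs.reads import BASES, DepthModel, simulate_mito_pileup

DEFAULT_MAF_BINS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclasses.dataclass
class TruthSet:
    """Simulation ground truth aligned to callable coordinates."""

    positions: np.ndarray
    genotypes: np.ndarray  # (M, N) in {0,1,2}

    @property
    def maf(self) -> np.ndarray:
        p = self.genotypes.mean(axis=1) / 2.0
        return np.minimum(p, 1 - p)

    @property
    def dosages(self) -> np.ndarray:
        return self.genotypes.astype(float)


@dataclasses.dataclass
class HoldoutDesign:
    """An every-k-th-site masking design over a three-way site intersection."""

    intersection: np.ndarray  # sorted positions common to target + panels
    masked_positions: np.ndarray
    k: int

    @property
    def masked_fraction(self) -> float:
        return len(self.masked_positions) / len(self.intersection)


# ---------------------------------------------------------------------------
# call-set level scores
# ---------------------------------------------------------------------------

def call_set_sensitivity_fdr(
    called_positions,
    called_maf,
    truth_positions,
    truth_maf,
    maf_bins=DEFAULT_MAF_BINS,
):
    """Per-MAF-bin sensitivity and FDR of a discovered site list.

    Sensitivity in a bin = |called AND truth| / |truth| over truth sites
    whose *truth* MAF falls in the bin; FDR = |called NOT truth| / |called|
    over called sites binned by their *call-set* MAF.  Bin edges are
    inclusive on the left.  Empty truth bins yield NaN sensitivity; an
    empty called bin yields NaN FDR.

    Returns a DataFrame (bin_low, bin_high, sensitivity, fdr) plus an
    overall row (bin bounds spanning the full range).
    """
    called_positions = np.asarray(called_positions)
    truth_positions = np.asarray(truth_positions)
    called_maf = np.asarray(called_maf, dtype=float)
    truth_maf = np.asarray(truth_maf, dtype=float)
    truth_set = set(truth_positions.tolist())
    called_set = set(called_positions.tolist())

    edges = list(maf_bins)
    rows = []
    spans = list(zip(edges[:-1], edges[1:])) + [(edges[0], edges[-1])]
    for lo, hi in spans:
        overall = (lo, hi) == (edges[0], edges[-1])
        in_bin_truth = (truth_maf >= lo) & (
            (truth_maf <= hi) if (hi == edges[-1]) else (truth_maf < hi)
        )
        n_truth = int(in_bin_truth.sum())
        if n_truth:
            tp = sum(
                1 for p in truth_positions[in_bin_truth] if p in called_set
            )
            sens = tp / n_truth
        else:
            sens = float("nan")
        in_bin_called = (called_maf >= lo) & (
            (called_maf <= hi) if (hi == edges[-1]) else (called_maf < hi)
        )
        n_called = int(in_bin_called.sum())
        if n_called:
            fp = sum(
                1 for p in called_positions[in_bin_called] if p not in truth_set
            )
            fdr = fp / n_called
        else:
            fdr = float("nan")
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "overall": overall,
                "n_truth": n_truth,
                "n_called": n_called,
                "sensitivity": sens,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)


def genotype_discordance(called, truth, depth=None):
    """Genotype discordance against truth, overall / per sample / strata.

    called, truth: (M, N) genotype matrices (MISSING in ``called`` counts
    as discordant: the pipeline is expected to emit a genotype everywhere
    after refinement).  With a depth matrix, cells are additionally
    stratified by (truth hom/het) x (depth zero/positive) and per-stratum
    accuracy = 1 - discordance is reported.

    Returns dict with keys overall, per_sample (array), strata (DataFrame
    or None).
    """
    called = np.asarray(called)
    truth = np.asarray(truth)
    mismatch = called != truth
    out = {
        "overall": float(mismatch.mean()),
        "per_sample": mismatch.mean(axis=0),
        "strata": None,
    }
    if depth is not None:
        depth = np.asarray(depth)
        rows = []
        for name, truth_mask in (
            ("hom", truth != 1),
            ("het", truth == 1),
        ):
            for dname, dmask in (("zero", depth == 0), ("covered", depth > 0)):
                cells = truth_mask & dmask
                n = int(cells.sum())
                disc = float(mismatch[cells].mean()) if n else float("nan")
                rows.append(
                    {
                        "truth": name,
                        "depth": dname,
                        "n_cells": n,
                        "discordance": disc,
                        "accuracy": 1.0 - disc if n else float("nan"),
                    }
                )
        out["strata"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# imputation holdout
# ---------------------------------------------------------------------------

def holdout_every_kth(
    target_positions, custom_positions, generic_positions, k: int = 20
) -> HoldoutDesign:
    """The every-k-th-site holdout design.

    The three site lists are intersected, sorted by position, and every
    k-th site (1-based indices divisible by k) is masked, deleting
    floor(|I|/k)/|I| (~5% at k=20) of the common sites.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    inter = np.array(
        sorted(
            set(np.asarray(target_positions).tolist())
            & set(np.asarray(custom_positions).tolist())
            & set(np.asarray(generic_positions).tolist())
        )
    )
    if inter.size == 0:
        raise ValueError("empty three-way site intersection")
    idx = np.arange(1, inter.size + 1)
    return HoldoutDesign(
        intersection=inter, masked_positions=inter[idx % k == 0], k=k
    )


def dosage_r2(imputed, truth) -> float:
    """Squared Pearson correlation between imputed and true dosages over
    all masked cells (flattened)."""
    x = np.asarray(imputed, dtype=float).ravel()
    y = np.asarray(truth, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 masked cells for dosage R^2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError(
            f"zero variance in dosage vectors (imputed sd={x.std():.3g}, "
            f"truth sd={y.std():.3g})"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def panel_comparison_experiment(
    truth_genotypes,
    positions,
    strata_labels,
    generic_panel: HaplotypePanel,
    targets_per_stratum: dict,
    k: int = 20,
    params: HmmParams | None = None,
    called_genotypes=None,
    seed=None,
):
    """Custom-vs-generic reference panel imputation comparison.

    For each stratum, ``targets_per_stratum[stratum]`` samples are drawn
    (seeded) as imputation targets; the custom panel is built from the
    haplotype-phased remaining cohort (here: truth haplotypes of the
    non-target samples, the population-matched panel), the generic panel
    is supplied by the caller (typically simulated at some divergence
    from the cohort).  The every-k-th holdout masks sites; both panels
    impute the masked cells; per-stratum dosage R^2 for both panels is
    returned along with the masked-site recovery rate (always expected 1:
    the copying model emits a dosage everywhere).

    ``truth_genotypes``: (M, N); ``called_genotypes`` optionally supplies
    the matrices actually imputed (defaults to truth, isolating panel
    effects from calling error).
    """
    params = params or HmmParams()
    rng = as_rng(seed)
    truth_genotypes = np.asarray(truth_genotypes)
    labels = np.asarray(strata_labels)
    positions = np.asarray(positions)
    observed = (
        truth_genotypes if called_genotypes is None else np.asarray(called_genotypes)
    )

    rows = []
    for stratum, n_targets in targets_per_stratum.items():
        members = np.flatnonzero(labels == stratum)
        if len(members) <= n_targets:
            warnings.warn(f"stratum {stratum!r} too small to split; skipped")
            continue
        targets = rng.choice(members, size=n_targets, replace=False)
        rest = np.array([i for i in range(truth_genotypes.shape[1]) if i not in set(targets)])

        design = holdout_every_kth(positions, positions, generic_panel.positions, k=k)
        masked_idx = np.flatnonzero(np.isin(positions, design.masked_positions))

        # custom panel: phased haplotypes of the remaining cohort
        custom_haps = _genotypes_to_pseudo_haplotypes(
            truth_genotypes[:, rest].T, rng
        )
        custom = HaplotypePanel(haplotypes=custom_haps, positions=positions)

        target_g = observed[:, targets].T  # (T, M)
        res = {}
        for name, panel in (("custom", custom), ("generic", generic_panel)):
            dos = impute_masked_sites(
                target_g, masked_idx, panel, params=params, seed=rng
            )
            truth_dos = truth_genotypes[masked_idx][:, targets].T.astype(float)
            res[f"r2_{name}"] = dosage_r2(dos, truth_dos)
            res[f"recovered_{name}"] = float(np.isfinite(dos).mean())
        rows.append({"stratum": stratum, "n_targets": n_targets, **res})
    return pd.DataFrame(rows)


def _genotypes_to_pseudo_haplotypes(genotypes, rng):
    """Split diploid genotypes into two pseudo-haplotypes per sample
    (random phase at hets) -- panel construction when true phase is not
    carried along."""
    g = np.asarray(genotypes)  # (N, M)
    n, m = g.shape
    flip = rng.random((n, m)) < 0.5
    het = g == 1
    h1 = np.where(g == 2, 1, 0).astype(np.uint8)
    h2 = h1.copy()
    h1[het] = flip[het]
    h2[het] = ~flip[het]
    out = np.empty((2 * n, m), dtype=np.uint8)
    out[0::2] = h1
    out[1::2] = h2
    return out


# ---------------------------------------------------------------------------
# mitochondrial contig
# ---------------------------------------------------------------------------

def mt_reference_sequence(length: int = 16569, seed: int = 7) -> str:
    """Synthetic circular mitochondrial reference (seeded random bases)."""
    rng = np.random.default_rng(seed)
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def synthetic_haplogroup_table(
    lineages=("M", "R", "U", "HV", "K"),
    mt_length: int = 16569,
    n_defining: int = 25,
    seed: int = 7,
) -> dict:
    """Synthetic haplogroup-defining variant table.

    Maps lineage -> list of (1-based position, derived base); positions are
    disjoint across lineages so scores separate cleanly.  Stands in for a
    real mitochondrial phylogeny; the lineage labels echo major South-Asian
    and West-Eurasian haplogroup names but the variants are synthetic.
    """
    rng = np.random.default_rng(seed)
    ref = mt_reference_sequence(mt_length, seed=seed)
    all_pos = rng.choice(mt_length, size=n_defining * len(lineages), replace=False) + 1
    table = {}
    for i, lineage in enumerate(lineages):
        pos = np.sort(all_pos[i * n_defining : (i + 1) * n_defining])
        entries = []
        for p in pos:
            base = ref[p - 1]
            alt = BASES[(BASES.index(base) + 1 + rng.integers(0, 3)) % 4]
            entries.append((int(p), alt))
        table[lineage] = entries
    return table


def haplogroup_sequence(reference: str, table: dict, lineage: str) -> str:
    """Apply a lineage's defining variants to the reference sequence."""
    seq = list(reference)
    for pos, base in table[lineage]:
        seq[pos - 1] = base
    return "".join(seq)


def mito_consensus(base_counts, min_depth: int = 10) -> str:
    """Majority-rule consensus: per position the majority base when depth
    exceeds ``min_depth``, else 'N'; exact ties are 'N'."""
    counts = np.asarray(base_counts)
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    top_count = counts.max(axis=1)
    tie = (counts == top_count[:, None]).sum(axis=1) > 1
    out = np.array([BASES[i] for i in top])
    out[(depth <= min_depth) | tie] = "N"
    return "".join(out)


def assign_haplogroup(consensus: str, table: dict):
    """Type a consensus sequence against a defining-variant table.

    score(h) = fraction of h's defining derived alleles matched at non-N
    consensus positions; the argmax lineage is assigned unless the best
    score is below 0.8 or tied, in which case "unassigned".
    Returns (label, best score).
    """
    if not table:
        raise ValueError("empty haplogroup table")
    scores = {}
    for lineage, entries in table.items():
        matched = sum(
            1
            for pos, base in entries
            if consensus[pos - 1] != "N" and consensus[pos - 1] == base
        )
        scores[lineage] = matched / len(entries)
    best = max(scores.values())
    winners = [h for h, s in scores.items() if s == best]
    if best < 0.8 or len(winners) > 1:
        return "unassigned", best
    return winners[0], best


def haplogroup_proportions(assignments, pop_labels) -> pd.DataFrame:
    """Per-population proportions of each assigned lineage (incl.
    'unassigned'), Fig-style population x lineage layout."""
    df = pd.DataFrame({"pop": pop_labels, "haplogroup": assignments})
    counts = df.groupby(["pop", "haplogroup"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def mito_cohort_summary(
    cohort,
    depth_model: DepthModel | None = None,
    table: dict | None = None,
    min_depth: int = 10,
    seed=None,
):
    """Simulate mtDNA pileups for a cohort, call consensus sequences, type
    haplogroups and summarise per-stratum lineage proportions."""
    depth_model = depth_model or DepthModel()
    table = table or synthetic_haplogroup_table(mt_length=cohort.mt_length)
    ref = mt_reference_sequence(cohort.mt_length)
    rng = as_rng(seed if seed is not None else derive_rng(cohort.seed, "mito"))
    assignments, mean_depths = [], []
    for _, row in cohort.samples.iterrows():
        true_seq = haplogroup_sequence(ref, table, row["mt_haplogroup"])
        counts = simulate_mito_pileup(
            true_seq, row["target_coverage"], depth_model, seed=rng
        )
        mean_depths.append(counts.sum(axis=1).mean())
        consensus = mito_consensus(counts, min_depth=min_depth)
        label, _ = assign_haplogroup(consensus, table)
        assignments.append(label)
    props = haplogroup_proportions(assignments, cohort.samples["stratum"])
    return {
        "assignments": assignments,
        "mean_depths": np.array(mean_depths),
        "proportions": props,
    }
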